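"""Run configuration shared by the partitioning pipeline, io and CLI."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

from .core import DEFAULT_RY_SUM_TOL, ComppartError

__all__ = ["RunConfig", "ABILITY_SOURCES", "MODELS"]

ABILITY_SOURCES = ("monoculture_full", "column", "monoculture_partial")
MODELS = ("competitive", "additive", "both")


@dataclass
class RunConfig:
    """Options controlling a partitioning run.

    ability_source
        Where the competitive-ability proxy H comes from:
        ``monoculture_full`` (default; H = full-density monoculture yield,
        as in both reference analyses), ``column`` (an explicit per-species
        ability value supplied in the data), or ``monoculture_partial``
        (H = partial-density monoculture yield; useful where full-density
        monocultures stagnate, e.g. pot-bound rooting volumes).
    model
        Which partitioning model(s) to run: ``competitive``, ``additive`` or
        ``both``.
    neutrality_band
        Relative half-width of the species-level neutral class: a species is
        "neutral" when |Y_O - Y_CE| <= band * max(Y_CE, Y_NE). A reporting
        convention only; community components never use it.
    ry_sum_tolerance
        Tolerance on sum(RY_E) = 1 before a non-replacement warning.
    fp_tolerance
        Relative tolerance for internal floating-point identity checks.
    multispecies_adjustment
        Apply the mid-ranked maximum-growth adjustment in mixtures of three
        or more species (experimental).
    response_curve
        Optional monotone function f(RC) replacing the linear response; the
        competitive expectation becomes Y_NE * (1 + MG * f(RC)). Default is
        the identity.
    mg_overrides
        Optional user-supplied maximum competitive growth responses keyed by
        (mixture_id, species_id); overrides the partial-density estimate,
        e.g. when derived from published density-yield relationships.
    round_digits
        If set, round values in written report tables to this many digits.
    """

    ability_source: str = "monoculture_full"
    model: str = "both"
    neutrality_band: float = 0.05
    ry_sum_tolerance: float = DEFAULT_RY_SUM_TOL
    fp_tolerance: float = 1e-9
    multispecies_adjustment: bool = False
    response_curve: Callable[[float], float] | None = None
    mg_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    round_digits: int | None = None
    output_format: str = "csv"

    def __post_init__(self) -> None:
        if self.ability_source not in ABILITY_SOURCES:
            raise ComppartError(
                f"ability_source must be one of {ABILITY_SOURCES}, "
                f"got {self.ability_source!r}"
            )
        if self.model not in MODELS:
            raise ComppartError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.neutrality_band < 0:
            raise ComppartError("neutrality_band must be >= 0")
        if self.output_format not in ("csv", "json"):
            raise ComppartError("output_format must be 'csv' or 'json'")
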