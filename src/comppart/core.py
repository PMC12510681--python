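"""Domain types and null-expectation arithmetic for mixture experiments.

A mixture experiment compares species grown together (mixtures) against the
same species grown alone (monocultures). Under the null hypothesis of
competitive equivalence, each species is expected to contribute its expected
relative yield times its full-density monoculture yield; the community-level
departure from that expectation is the net biodiversity effect. These types
and functions are shared by both the additive (complementarity/selection) and
the competitive partitioning models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SpeciesReference",
    "MixtureObservation",
    "MixtureCommunity",
    "MixtureDataset",
    "Diagnostic",
    "ComppartError",
    "ComppartWarning",
    "validate_dataset",
    "individual_size",
    "null_expectation",
    "net_biodiversity_effect",
]

#: Default tolerance on the sum of expected relative yields in a replacement design.
DEFAULT_RY_SUM_TOL = 1e-6


class ComppartError(ValueError):
    """Domain error raised for inputs outside the model's domain."""


class ComppartWarning(UserWarning):
    """Non-fatal model warning (e.g. a dominant species shrinking at low density)."""


@dataclass(frozen=True)
class SpeciesReference:
    """Monoculture information for one species in one experimental context.

    Parameters
    ----------
    species_id
        Species label.
    mono_full_yield
        Full-density monoculture yield ``M_if`` (biomass or volume per pot
        or per unit area).
    density_full
        Planting density of the full-density monoculture (individuals per
        pot or per unit area); the replacement design plants mixtures at
        this same total density.
    ability
        Competitive-ability proxy ``H_i`` (same units as yields). When
        omitted, the full-density monoculture yield is used: more productive
        species are assumed more competitive.
    """

    species_id: str
    mono_full_yield: float
    density_full: float
    ability: float | None = None

    def __post_init__(self) -> None:
        if self.mono_full_yield < 0:
            raise ComppartError(
                f"mono_full_yield must be >= 0 for {self.species_id!r}"
            )
        if self.density_full <= 0:
            raise ComppartError(f"density_full must be > 0 for {self.species_id!r}")
        if self.ability is not None and self.ability < 0:
            raise ComppartError(f"ability must be >= 0 for {self.species_id!r}")

    @property
    def size_full(self) -> float:
        """Per-capita size w_if in the full-density monoculture."""
        return individual_size(self.mono_full_yield, self.density_full)


@dataclass(frozen=True)
class MixtureObservation:
    """One species' record within one mixture.

    ``ry_expected`` is the species' expected relative yield (its planted
    proportion in a replacement design); ``yield_observed`` its measured
    yield in the mixture. ``mono_partial_yield`` is the yield of a
    monoculture planted at this species' density within the mixture
    (the partial-density monoculture ``M_ip``), required to estimate the
    maximum competitive growth response of dominant species.
    """

    species_id: str
    ry_expected: float
    yield_observed: float
    mono_partial_yield: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.ry_expected <= 1:
            raise ComppartError(
                f"ry_expected must be in (0, 1] for {self.species_id!r}, "
                f"got {self.ry_expected}"
            )
        if self.yield_observed < 0:
            raise ComppartError(f"yield_observed must be >= 0 for {self.species_id!r}")
        if self.mono_partial_yield is not None and self.mono_partial_yield < 0:
            raise ComppartError(
                f"mono_partial_yield must be >= 0 for {self.species_id!r}"
            )


@dataclass(frozen=True)
class MixtureCommunity:
    """One mixture: total planting density plus per-species observations.

    ``references`` maps each observed species to its monoculture reference
    valid in this context. References are attached per community rather than
    per dataset so that the same species can have different monoculture
    yields in different contexts (e.g. a chronosequence where monoculture
    stand volume grows with age).
    """

    mixture_id: str
    density_total: float
    observations: tuple[MixtureObservation, ...]
    references: Mapping[str, SpeciesReference]
    age_or_time: str | None = None

    def __post_init__(self) -> None:
        if self.density_total <= 0:
            raise ComppartError(f"{self.mixture_id}: density_total must be > 0")
        ids = [o.species_id for o in self.observations]
        if len(set(ids)) < 2:
            raise ComppartError(
                f"{self.mixture_id}: a mixture needs >= 2 distinct species"
            )
        if len(set(ids)) != len(ids):
            raise ComppartError(f"{self.mixture_id}: duplicated species in mixture")

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(o.species_id for o in self.observations)

    @property
    def n_species(self) -> int:
        return len(self.observations)

    def reference(self, species_id: str) -> SpeciesReference:
        try:
            return self.references[species_id]
        except KeyError:
            raise ComppartError(
                f"{self.mixture_id}: no monoculture reference for {species_id!r}"
            ) from None

    def partial_density(self, species_id: str) -> float:
        """Species density within the mixture, RY_E * total density."""
        obs = self.observation(species_id)
        return obs.ry_expected * self.density_total

    def observation(self, species_id: str) -> MixtureObservation:
        for o in self.observations:
            if o.species_id == species_id:
                return o
        raise ComppartError(f"{self.mixture_id}: species {species_id!r} not observed")

    @property
    def total_observed(self) -> float:
        return sum(o.yield_observed for o in self.observations)


@dataclass
class MixtureDataset:
    """A collection of mixture communities sharing yield and density units."""

    communities: list[MixtureCommunity] = field(default_factory=list)
    yield_units: str = "yield"
    density_units: str = "individuals"

    @property
    def species(self) -> set[SpeciesReference]:
        """Union of all per-community species references."""
        return {r for c in self.communities for r in c.references.values()}

    @property
    def species_ids(self) -> set[str]:
        return {s for c in self.communities for s in c.species_ids}

    def __len__(self) -> int:
        return len(self.communities)

    def __iter__(self):
        return iter(self.communities)


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding. ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    mixture_id: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"[{self.mixture_id}] " if self.mixture_id else ""
        return f"{self.severity.upper()}: {where}{self.message}"


def validate_dataset(
    dataset: MixtureDataset, ry_sum_tol: float = DEFAULT_RY_SUM_TOL
) -> list[Diagnostic]:
    """Check every community against the model's invariants.

    Errors block partitioning (missing monoculture references, non-positive
    densities); deviations from the replacement design (expected relative
    yields not summing to 1) are warnings so that additive-design experiments
    remain admissible.
    """
    out: list[Diagnostic] = []
    if not dataset.communities:
        out.append(Diagnostic("error", None, "dataset contains no mixtures"))
        return out
    for com in dataset.communities:
        for obs in com.observations:
            if obs.species_id not in com.references:
                out.append(
                    Diagnostic(
                        "error",
                        com.mixture_id,
                        f"species {obs.species_id!r} lacks a monoculture reference "
                        "(mono_full_yield required)",
                    )
                )
            if com.partial_density(obs.species_id) <= 0:
                out.append(
                    Diagnostic(
                        "error",
                        com.mixture_id,
                        f"partial density of {obs.species_id!r} is not positive",
                    )
                )
        ry_sum = sum(o.ry_expected for o in com.observations)
        if abs(ry_sum - 1.0) > ry_sum_tol:
            out.append(
                Diagnostic(
                    "warning",
                    com.mixture_id,
                    f"non-replacement composition: expected relative yields sum "
                    f"to {ry_sum:g}, not 1",
                )
            )
    return out


def individual_size(yield_: float, density: float) -> float:
    """Per-capita size: yield divided by planting density.

    Raises a domain error for non-positive density.
    """
    if density <= 0:
        raise ComppartError(f"density must be > 0, got {density}")
    return yield_ / density


def null_expectation(
    community: MixtureCommunity,
    references: Mapping[str, SpeciesReference] | None = None,
) -> dict[str, float]:
    """Per-species null-expected yields Y_NE = RY_E * M_if.

    The null hypothesis assumes competitive equivalence: each species yields
    in mixture exactly its expected share of its full-density monoculture.
    """
    refs = references if references is not None else community.references
    out: dict[str, float] = {}
    for obs in community.observations:
        if obs.species_id not in refs:
            raise ComppartError(
                f"{community.mixture_id}: missing full-density monoculture yield "
                f"for {obs.species_id!r}"
            )
        out[obs.species_id] = obs.ry_expected * refs[obs.species_id].mono_full_yield
    return out


def net_biodiversity_effect(
    community: MixtureCommunity,
    references: Mapping[str, SpeciesReference] | None = None,
) -> float:
    """Observed total yield minus total null expectation."""
    y_ne = null_expectation(community, references)
    return community.total_observed - sum(y_ne.values())


def isclose_abs(a: float, b: float, scale: float, rel: float = 1e-9) -> bool:
    """Absolute comparison at a tolerance scaled to the largest input magnitude."""
    return math.isclose(a, b, rel_tol=0.0, abs_tol=rel * max(abs(scale), 1e-300))


def make_two_species_community(
    mixture_id: str,
    m_full: Sequence[float],
    y_obs: Sequence[float],
    m_partial: Sequence[float | None] | None = None,
    ry: Sequence[float] = (0.5, 0.5),
    density_full: float = 6.0,
    density_total: float | None = None,
    species_ids: Sequence[str] = ("sp1", "sp2"),
    abilities: Sequence[float | None] | None = None,
    age_or_time: str | None = None,
) -> MixtureCommunity:
    """Convenience constructor for small (mostly two-species) communities."""
    n = len(m_full)
    m_partial = m_partial if m_partial is not None else [None] * n
    abilities = abilities if abilities is not None else [None] * n
    refs = {
        sid: SpeciesReference(sid, mf, density_full, ability=h)
        for sid, mf, h in zip(species_ids, m_full, abilities)
    }
    obs = tuple(
        MixtureObservation(sid, r, y, mono_partial_yield=mp)
        for sid, r, y, mp in zip(species_ids, ry, y_obs, m_partial)
    )
    return MixtureCommunity(
        mixture_id,
        density_total if density_total is not None else density_full,
        obs,
        refs,
        age_or_time=age_or_time,
    )
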