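"""Competitive partitioning of net biodiversity effects.

The model modifies the null expectation with a competitive growth response:
under a pure resource-competition hypothesis each species' expected mixture
yield is

    Y_CE_i = Y_NE_i * (1 + MG_i * RC_i)

where MG_i is the maximum competitive growth response — the proportional
change in per-capita size from the full-density monoculture to the
partial-density monoculture (w_ip / w_if - 1) for species more competitive
than the community average, and -1 (competitive exclusion) for less
competitive species — and RC_i scales that maximum by how far the species'
competitive ability H_i deviates from the mean ability of the other species,
relative to the community maximum:

    RC_i = |H_i - mean(H_j, j != i)| / max(H)

At the community level the net biodiversity effect splits exactly into

    net = positive + negative + competitive

with competitive = sum(Y_CE) - sum(Y_NE), and positive/negative the
(sign-separated) deviation of the observed total from the competitive
expectation. The BPM statistic — the partial-density monoculture yield of the
most competitive species minus the total null expectation — measures how much
of a mixture's apparent biodiversity effect could be had from a thinned
monoculture of the dominant alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .config import RunConfig
from .core import (
    ComppartError,
    ComppartWarning,
    MixtureCommunity,
    MixtureObservation,
    SpeciesReference,
    individual_size,
    null_expectation,
)

__all__ = [
    "CompetitiveResponse",
    "SpeciesPartition",
    "CompetitivePartition",
    "relative_competitive_ability",
    "max_growth_response",
    "multispecies_mg_adjustment",
    "competitive_responses",
    "competitive_expectation",
    "partition_community",
    "bpm_statistic",
    "classify_species",
    "pair_interaction_label",
]

INTERACTION_CLASSES = ("facilitative", "positive", "neutral", "negative")


@dataclass(frozen=True)
class CompetitiveResponse:
    """Per-species competitive growth response inside one mixture."""

    species_id: str
    w_if: float
    w_ip: float | None
    mg: float
    rc: float
    is_more_competitive: bool
    ability: float
    ability_mean_others: float
    ability_max: float


@dataclass(frozen=True)
class SpeciesPartition:
    """Species-level outcome: expectations, response terms and class label."""

    species_id: str
    y_ne: float
    y_ce: float
    y_obs: float
    mg: float
    rc: float
    deviation: float
    interaction_class: str


@dataclass(frozen=True)
class CompetitivePartition:
    """Community-level competitive partition of the net biodiversity effect."""

    mixture_id: str
    species: tuple[SpeciesPartition, ...]
    net: float
    positive_effect: float
    competitive_effect: float
    negative_effect: float
    bpm: float
    bpm_by_species: dict[str, float]
    pair_label: str | None = None

    @property
    def combined_comp_neg(self) -> float:
        """Competitive plus negative effect, the single column some reports use."""
        return self.competitive_effect + self.negative_effect


def relative_competitive_ability(
    abilities: Mapping[str, float],
) -> dict[str, float]:
    """RC_i = |H_i - mean of the others' H| / max(H).

    Dimensionless in [0, 1]; zero exactly when a species sits at the mean
    ability of its companions. For two species both share the same RC.
    """
    if len(abilities) < 2:
        raise ComppartError("relative competitive ability needs >= 2 species")
    if any(h < 0 for h in abilities.values()):
        raise ComppartError("abilities must be >= 0")
    h_max = max(abilities.values())
    if h_max <= 0:
        raise ComppartError("all abilities are zero; RC undefined")
    out: dict[str, float] = {}
    for sid, h in abilities.items():
        others = [v for k, v in abilities.items() if k != sid]
        out[sid] = abs(h - sum(others) / len(others)) / h_max
    return out


def max_growth_response(
    ref: SpeciesReference,
    mono_partial_yield: float | None,
    partial_density: float,
    is_more_competitive: bool,
) -> float:
    """Maximum competitive growth response MG under competitive exclusion.

    A more competitive species completely dominating the mixture grows like
    its partial-density monoculture, so its per-capita size may rise by up to
    w_ip / w_if - 1; a less competitive species is excluded, losing all of
    its size (-1).
    """
    if not is_more_competitive:
        return -1.0
    if mono_partial_yield is None:
        raise ComppartError(
            f"species {ref.species_id!r} is more competitive but has no "
            "partial-density monoculture yield; supply mono_partial_yield or "
            "an MG override"
        )
    w_if = ref.size_full
    if w_if <= 0:
        raise ComppartError(
            f"per-capita full-density size of {ref.species_id!r} must be > 0"
        )
    w_ip = individual_size(mono_partial_yield, partial_density)
    mg = w_ip / w_if - 1.0
    if mg < 0:
        warnings.warn(
            f"more competitive species {ref.species_id!r} is smaller at partial "
            f"density (MG = {mg:.4g} < 0); no growth release at lower density",
            ComppartWarning,
            stacklevel=2,
        )
    return mg


def multispecies_mg_adjustment(
    mg: float,
    ry_expected_self: float,
    ry_expected_more_competitive: Iterable[float],
) -> float:
    """Shrink MG for a mid-ranked species in mixtures of three or more.

    With other, stronger competitors holding shares RY_Ej, the resource gain
    available to species i is (1 - sum RY_Ej)/RY_Ei - 1 rather than
    1/RY_Ei - 1; the partial-density MG is scaled by the ratio of the two.
    The top-ranked species (empty j-set) is unchanged; the result is clamped
    at -1.
    """
    stronger = list(ry_expected_more_competitive)
    if not stronger:
        return mg
    if ry_expected_self >= 1.0:
        raise ComppartError("RY_E of an adjusted species must be < 1")
    full_gain = 1.0 / ry_expected_self - 1.0
    avail_gain = (1.0 - sum(stronger)) / ry_expected_self - 1.0
    scale = avail_gain / full_gain
    return max(-1.0, mg * scale)


def _resolve_abilities(
    community: MixtureCommunity, config: RunConfig
) -> dict[str, float]:
    out: dict[str, float] = {}
    for obs in community.observations:
        ref = community.reference(obs.species_id)
        if config.ability_source == "monoculture_full":
            h = ref.ability if ref.ability is not None else ref.mono_full_yield
        elif config.ability_source == "column":
            if ref.ability is None:
                raise ComppartError(
                    f"{community.mixture_id}: ability_source='column' but species "
                    f"{obs.species_id!r} has no ability value"
                )
            h = ref.ability
        else:  # monoculture_partial
            if obs.mono_partial_yield is None:
                raise ComppartError(
                    f"{community.mixture_id}: ability_source='monoculture_partial' "
                    f"but {obs.species_id!r} has no partial-density yield"
                )
            h = obs.mono_partial_yield
        out[obs.species_id] = h
    return out


def competitive_responses(
    community: MixtureCommunity, config: RunConfig | None = None
) -> dict[str, CompetitiveResponse]:
    """Compute MG and RC for every species in a mixture.

    A species counts as "more competitive" when its ability exceeds the mean
    ability of the other species; at an exact tie RC = 0 makes the response
    term inert and MG is reported as 0 by convention.
    """
    config = config or RunConfig()
    abilities = _resolve_abilities(community, config)
    rc = relative_competitive_ability(abilities)
    h_max = max(abilities.values())
    out: dict[str, CompetitiveResponse] = {}
    ranked = sorted(abilities, key=abilities.get, reverse=True)
    for obs in community.observations:
        sid = obs.species_id
        ref = community.reference(sid)
        others = [abilities[k] for k in abilities if k != sid]
        mean_others = sum(others) / len(others)
        diff = abilities[sid] - mean_others
        more = diff > 0
        override = config.mg_overrides.get((community.mixture_id, sid))
        if override is not None:
            mg = max(-1.0, override)
        elif diff == 0:
            mg = 0.0
        else:
            mg = max_growth_response(
                ref, obs.mono_partial_yield, community.partial_density(sid), more
            )
            if config.multispecies_adjustment and more and community.n_species >= 3:
                stronger = [
                    community.observation(k).ry_expected
                    for k in ranked
                    if abilities[k] > abilities[sid]
                ]
                mg = multispecies_mg_adjustment(mg, obs.ry_expected, stronger)
        w_ip = (
            individual_size(obs.mono_partial_yield, community.partial_density(sid))
            if obs.mono_partial_yield is not None
            else None
        )
        out[sid] = CompetitiveResponse(
            species_id=sid,
            w_if=ref.size_full,
            w_ip=w_ip,
            mg=mg,
            rc=rc[sid],
            is_more_competitive=more,
            ability=abilities[sid],
            ability_mean_others=mean_others,
            ability_max=h_max,
        )
    return out


def competitive_expectation(
    community: MixtureCommunity,
    responses: Mapping[str, CompetitiveResponse],
    config: RunConfig | None = None,
) -> dict[str, float]:
    """Per-species competitive expectations Y_CE = Y_NE * (1 + MG * f(RC))."""
    config = config or RunConfig()
    f = config.response_curve or (lambda rc: rc)
    y_ne = null_expectation(community)
    return {
        sid: y_ne[sid] * (1.0 + responses[sid].mg * f(responses[sid].rc))
        for sid in y_ne
    }


def classify_species(
    observation: MixtureObservation,
    y_ne: float,
    y_ce: float,
    config: RunConfig | None = None,
) -> str:
    """Species-level interaction class from yields and expectations.

    ``facilitative`` when the species outyields its own partial-density
    monoculture (it does better in mixture than alone at the same density);
    otherwise ``positive``/``neutral``/``negative`` by the sign of
    Y_O - Y_CE inside a relative neutrality band. Without a partial-density
    monoculture the facilitation test is skipped with a warning.
    """
    config = config or RunConfig()
    if observation.mono_partial_yield is None:
        warnings.warn(
            f"no partial-density monoculture for {observation.species_id!r}; "
            "facilitation test skipped",
            ComppartWarning,
            stacklevel=2,
        )
    elif observation.yield_observed > observation.mono_partial_yield:
        return "facilitative"
    dev = observation.yield_observed - y_ce
    band = config.neutrality_band * max(abs(y_ce), abs(y_ne))
    if abs(dev) <= band:
        return "neutral"
    return "positive" if dev > 0 else "negative"


def pair_interaction_label(classes: tuple[str, str]) -> str | None:
    """Two-species pair label: mutualism (+/+), commensalism (+/0), parasitism (+/-).

    Assigned only when at least one species benefits (facilitative or
    positive); pairs without a benefiting species get no label.
    """
    sign = {"facilitative": "+", "positive": "+", "neutral": "0", "negative": "-"}
    a, b = (sign[c] for c in classes)
    pair = "".join(sorted((a, b), key="+0-".index))
    return {
        "++": "mutualism (+/+)",
        "+0": "commensalism (+/0)",
        "+-": "parasitism (+/-)",
    }.get(pair)


def _bpm_candidates(
    community: MixtureCommunity, abilities: Mapping[str, float]
) -> dict[str, float]:
    h_max = max(abilities.values())
    top = [sid for sid, h in abilities.items() if h == h_max]
    y_ne_total = sum(null_expectation(community).values())
    out: dict[str, float] = {}
    for sid in top:
        m_ip = community.observation(sid).mono_partial_yield
        if m_ip is None:
            raise ComppartError(
                f"{community.mixture_id}: most competitive species {sid!r} has no "
                "partial-density monoculture yield; BPM undefined"
            )
        out[sid] = m_ip - y_ne_total
    return out


def bpm_statistic(
    community: MixtureCommunity, config: RunConfig | None = None
) -> float:
    """Partial-density monoculture yield of the most competitive species minus
    the total null expectation. Ties for most competitive are resolved by
    reporting the maximum over the tied species."""
    config = config or RunConfig()
    abilities = _resolve_abilities(community, config)
    return max(_bpm_candidates(community, abilities).values())


def partition_community(
    community: MixtureCommunity, config: RunConfig | None = None
) -> CompetitivePartition:
    """Full competitive partition of one mixture.

    Community components satisfy net = positive + negative + competitive
    exactly: competitive is the shift of the expectation under pure resource
    competition, and the residual deviation of the observed total from the
    competitive expectation is attributed to dominance of positive
    (if > 0) or negative (if < 0) interactions.
    """
    config = config or RunConfig()
    try:
        responses = competitive_responses(community, config)
        y_ne = null_expectation(community)
        y_ce = competitive_expectation(community, responses, config)
        abilities = _resolve_abilities(community, config)
    except ComppartError as err:
        raise ComppartError(f"{community.mixture_id}: {err}") from err
    try:
        bpm_by_species = _bpm_candidates(community, abilities)
    except ComppartError:
        # BPM needs the dominant's partial-density monoculture; with MG
        # supplied externally the partition itself is still well defined.
        warnings.warn(
            f"{community.mixture_id}: BPM unavailable (dominant species has no "
            "partial-density monoculture yield)",
            ComppartWarning,
            stacklevel=2,
        )
        bpm_by_species = {}

    species: list[SpeciesPartition] = []
    for obs in community.observations:
        sid = obs.species_id
        species.append(
            SpeciesPartition(
                species_id=sid,
                y_ne=y_ne[sid],
                y_ce=y_ce[sid],
                y_obs=obs.yield_observed,
                mg=responses[sid].mg,
                rc=responses[sid].rc,
                deviation=obs.yield_observed - y_ce[sid],
                interaction_class=classify_species(obs, y_ne[sid], y_ce[sid], config),
            )
        )

    total_obs = community.total_observed
    total_ne = sum(y_ne.values())
    total_ce = sum(y_ce.values())
    deviation = total_obs - total_ce
    pair = (
        pair_interaction_label(tuple(s.interaction_class for s in species))
        if len(species) == 2
        else None
    )
    return CompetitivePartition(
        mixture_id=community.mixture_id,
        species=tuple(species),
        net=total_obs - total_ne,
        positive_effect=max(0.0, deviation),
        competitive_effect=total_ce - total_ne,
        negative_effect=min(0.0, deviation),
        bpm=max(bpm_by_species.values()) if bpm_by_species else float("nan"),
        bpm_by_species=bpm_by_species,
        pair_label=pair,
    )
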