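"""Additive partitioning of net biodiversity effects (complementarity + selection).

The classical covariance decomposition splits the net effect
``sum(dRY_i * M_if)`` into a complementarity effect proportional to the mean
relative-yield deviation and a selection effect proportional to the covariance
between relative-yield deviations and monoculture yields:

    CE = N * mean(dRY) * mean(M_if)
    SE = N * cov(dRY, M_if)          (population covariance, divisor N)

so that CE + SE equals the net effect exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ComppartError, MixtureCommunity, net_biodiversity_effect

__all__ = ["AdditiveComponents", "delta_relative_yield", "additive_partition"]


@dataclass(frozen=True)
class AdditiveComponents:
    """Additive partition of one mixture's net biodiversity effect."""

    mixture_id: str
    n_species: int
    delta_ry: dict[str, float]
    ry_observed: dict[str, float]
    net: float
    complementarity: float
    selection: float


def delta_relative_yield(community: MixtureCommunity) -> dict[str, float]:
    """Per-species deviation of observed from expected relative yield.

    dRY_i = Y_Oi / M_if - RY_Ei. Requires a strictly positive full-density
    monoculture yield for every species, since observed relative yield is a
    ratio to it.
    """
    out: dict[str, float] = {}
    for obs in community.observations:
        ref = community.reference(obs.species_id)
        if ref.mono_full_yield <= 0:
            raise ComppartError(
                f"{community.mixture_id}: full-density monoculture yield of "
                f"{obs.species_id!r} must be > 0 for relative yields"
            )
        out[obs.species_id] = obs.yield_observed / ref.mono_full_yield - obs.ry_expected
    return out


def additive_partition(community: MixtureCommunity) -> AdditiveComponents:
    """Split the net biodiversity effect into complementarity and selection.

    The selection effect is returned as ``net - CE``, which equals
    ``N * cov_pop(dRY, M_if)`` algebraically; computing it by difference keeps
    the identity CE + SE = net exact in floating point.
    """
    d_ry = delta_relative_yield(community)
    ids = list(d_ry)
    dr = np.array([d_ry[s] for s in ids])
    mf = np.array([community.reference(s).mono_full_yield for s in ids])
    ry_obs = {
        s: community.observation(s).yield_observed
        / community.reference(s).mono_full_yield
        for s in ids
    }
    n = len(ids)
    net = net_biodiversity_effect(community)
    ce = n * dr.mean() * mf.mean()
    se = net - ce
    return AdditiveComponents(
        mixture_id=community.mixture_id,
        n_species=n,
        delta_ry=d_ry,
        ry_observed=ry_obs,
        net=net,
        complementarity=float(ce),
        selection=float(se),
    )
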