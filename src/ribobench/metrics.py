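"""Allele-to-allele structural disruption scores.

Four metrics quantify how much an SNV perturbs the predicted structure of
its window, all oriented so that larger means more disruption:

``bppm_profile``
    Alignment-free profile distance between base-pairing probability
    matrices: per base, one minus the Bhattacharyya coefficient between
    the two (upstream, downstream, unpaired) pairing distributions, summed
    over bases::

        d = sum_i [ 1 - ( sqrt(p1_i^( p2_i^() + sqrt(p1_i^) p2_i^))
                          + sqrt(p1_i^o p2_i^o) ) ]

    Bounded by the window length; 0 iff the profiles coincide.

``pearson_profile``
    1 - r, where r is the Pearson correlation between the two per-base
    total-pairing vectors (1 - p^o), the comparison style used by
    mutation-scoring tools built on pairing-probability correlation.

``relent_profile``
    Symmetrised Kullback--Leibler (Jeffreys) divergence between the two
    per-base 3-category pairing distributions, summed over bases, with
    additive epsilon smoothing: a stand-in for relative-entropy scoring
    between the two allele ensembles.

``mfe_bp``
    Size of the symmetric difference between the two MFE structures' base
    pair sets.

All metrics require equal-length inputs, are symmetric, non-negative, and
zero on identical inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fold import (
    BPPM,
    EnergyModel,
    PairingProfile,
    SecondaryStructure,
    mfe_structure,
    pair_probabilities,
    pairing_profile,
)
from .windows import SequenceWindow

__all__ = [
    "AlleleDistance",
    "METRICS",
    "bppm_profile_distance",
    "pearson_profile_distance",
    "relent_profile_distance",
    "mfe_bp_distance",
    "score_window",
]

METRICS = ("bppm_profile", "pearson_profile", "relent_profile", "mfe_bp")

DEFAULT_RELENT_EPS = 1e-6


@dataclass(frozen=True)
class AlleleDistance:
    """A disruption score for one window under one metric.

    Higher always means more predicted structural disruption.
    """

    window_id: str
    metric: str
    score: float
    higher_means_more_disruption: bool = True

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not np.isfinite(self.score) or self.score < -1e-9:
            raise ValueError(f"score must be finite and non-negative, got {self.score}")


def _check_lengths(a, b):
    if a.length != b.length:
        raise ValueError(
            f"profiles/structures must have equal length ({a.length} != {b.length})"
        )


def bppm_profile_distance(prof1: PairingProfile, prof2: PairingProfile) -> float:
    """Alignment-free pairing-profile distance (see module docstring).

    Sums, over bases, one minus the Bhattacharyya coefficient of the two
    (up, down, unpaired) distributions.  Ranges over [0, n].
    """
    _check_lengths(prof1, prof2)
    bc = (
        np.sqrt(prof1.up * prof2.up)
        + np.sqrt(prof1.down * prof2.down)
        + np.sqrt(prof1.unpaired * prof2.unpaired)
    )
    return float(np.sum(1.0 - bc))


def pearson_profile_distance(prof1: PairingProfile, prof2: PairingProfile) -> float:
    """1 - Pearson r between per-base total-pairing vectors; range [0, 2].

    Degenerate inputs: two constant, equal vectors score 0 (no disruption
    detectable); exactly one constant vector scores 1 (r treated as 0)
    with a warning, as correlation is undefined there.
    """
    _check_lengths(prof1, prof2)
    if prof1.length < 2:
        raise ValueError("pearson_profile_distance requires length >= 2")
    x = prof1.total_pairing()
    y = prof2.total_pairing()
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0.0 and sy == 0.0:
        if np.allclose(x, y):
            return 0.0
        warnings.warn(
            "both pairing vectors constant but unequal; correlation undefined, "
            "returning distance 1",
            stacklevel=2,
        )
        return 1.0
    if sx == 0.0 or sy == 0.0:
        warnings.warn(
            "one pairing vector is constant; correlation undefined, treating "
            "r as 0 (distance 1)",
            stacklevel=2,
        )
        return 1.0
    r = float(np.dot(xc, yc) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    return 1.0 - r


def relent_profile_distance(
    prof1: PairingProfile, prof2: PairingProfile, eps: float = DEFAULT_RELENT_EPS
) -> float:
    """Symmetrised per-base KL divergence over (up, down, unpaired).

    Each base's 3-category distribution is smoothed additively by *eps*
    and renormalised before computing KL(p||q) + KL(q||p); the per-base
    divergences are summed.  Zero iff the profiles are equal.
    """
    _check_lengths(prof1, prof2)
    p = np.stack([prof1.up, prof1.down, prof1.unpaired])
    q = np.stack([prof2.up, prof2.down, prof2.unpaired])
    p = (p + eps) / (1.0 + 3.0 * eps)
    q = (q + eps) / (1.0 + 3.0 * eps)
    log_ratio = np.log(p) - np.log(q)
    return float(np.sum((p - q) * log_ratio))


def mfe_bp_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Symmetric-difference size between two MFE structures' pair sets."""
    if len(s1) != len(s2):
        raise ValueError(
            f"structures must have equal length ({len(s1)} != {len(s2)})"
        )
    return len(s1.pairs ^ s2.pairs)


def score_window(
    window: SequenceWindow,
    model: EnergyModel,
    metric: str,
    ref_bppm: Optional[BPPM] = None,
    alt_bppm: Optional[BPPM] = None,
) -> AlleleDistance:
    """Fold both alleles of a window and apply the chosen metric.

    Externally computed BPPMs (e.g. imported through the exchange format
    from a third-party folder) may be supplied to bypass the internal
    folding engine for the profile metrics.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "mfe_bp":
        s1 = mfe_structure(window.ref_seq, model)
        s2 = mfe_structure(window.alt_seq, model)
        return AlleleDistance(window.window_id, metric, float(mfe_bp_distance(s1, s2)))
    b1 = ref_bppm if ref_bppm is not None else pair_probabilities(window.ref_seq, model)
    b2 = alt_bppm if alt_bppm is not None else pair_probabilities(window.alt_seq, model)
    p1 = pairing_profile(b1)
    p2 = pairing_profile(b2)
    if metric == "bppm_profile":
        score = bppm_profile_distance(p1, p2)
    elif metric == "pearson_profile":
        score = pearson_profile_distance(p1, p2)
    else:
        score = relent_profile_distance(p1, p2)
    return AlleleDistance(window.window_id, metric, max(score, 0.0))
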