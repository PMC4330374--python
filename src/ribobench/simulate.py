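"""Synthetic trio-PARS benchmark data with known ground truth.

Emulates the statistical shape of a family-trio PARS riboSNitch screen so
that every pipeline stage is testable without external downloads:

* each SNV sits at the centre of a window embedding a designed hairpin —
  a structure-disrupting SNV falls mid-stem (it breaks a Watson–Crick
  pair), a neutral one falls mid-loop;
* trio genotypes are drawn to realise the requested mixture of symmetric
  and asymmetric riboSNitches and of allele-specific-validation-eligible
  configurations (parents homozygous different, child heterozygous);
* each applicable pairwise comparison gets an FDR-adjusted P-value drawn
  from a Beta distribution — sharply small for comparisons that called a
  structure change, concentrated near 1 for those that did not;
* ``noise_frac`` injects "environmental" riboSNitches: windows labelled
  riboSNitch whose SNV is structurally neutral, the failure mode expected
  of structure changes driven by cellular context rather than
  thermodynamics.  Raising it degrades achievable prediction accuracy
  toward chance.

The sequence alphabet avoids U entirely (flanks and loops over {A, C},
stems over {G, C} with complementary strands) so that a mid-stem G→A
substitution removes its pair and cannot pair elsewhere, while a mid-loop
A→C substitution leaves the dominant hairpin intact.

All randomness flows through one seeded generator; the same seed yields
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .fold import RnaSequence
from .windows import SNVRecord, PAIR_KEYS

__all__ = ["SimConfig", "SimulatedDataset", "make_hairpin_window",
           "simulate_trio_dataset"]

_COMPLEMENT = {"G": "C", "C": "G"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated trio-PARS screen.

    Beta defaults: comparisons that called a structure change draw
    adjusted P from Beta(1, 20) (mass near 0); comparisons that did not
    draw from Beta(5, 1) (mass near 1).
    """

    n_ribosnitch: int = 200
    n_non: int = 200
    window_len: int = 101
    stem_len: int = 6
    loop_len: int = 4
    frac_symmetric: float = 0.5
    frac_validated_eligible: float = 0.3
    frac_probed: float = 0.05
    p_alpha_pos: float = 1.0
    p_beta_pos: float = 20.0
    p_alpha_neg: float = 5.0
    p_beta_neg: float = 1.0
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ribosnitch < 0 or self.n_non < 0:
            raise ValueError("counts must be >= 0")
        if self.window_len % 2 == 0:
            raise ValueError("window_len must be odd (SNV sits at the centre)")
        for name in ("frac_symmetric", "frac_validated_eligible", "frac_probed",
                     "noise_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("p_alpha_pos", "p_beta_pos", "p_alpha_neg", "p_beta_neg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stem_len < 3:
            raise ValueError("stem_len must be >= 3")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")


@dataclass
class HairpinWindow:
    """A generated window template: both allele sequences and SNV placement."""

    ref_bases: str
    alt_bases: str
    snv_offset: int  # 1-based, always the window centre
    disruptive: bool

    @property
    def ref_allele(self) -> str:
        return self.ref_bases[self.snv_offset - 1]

    @property
    def alt_allele(self) -> str:
        return self.alt_bases[self.snv_offset - 1]


def make_hairpin_window(
    cfg: SimConfig, rng: np.random.Generator, disruptive: bool = True
) -> HairpinWindow:
    """One window with a central hairpin and an SNV at the window centre.

    The hairpin (stem_len complementary stem, loop_len loop) is positioned
    so that the mutated base lands exactly at the centre: mid-stem for a
    disruptive SNV (ref G paired to C across the loop, alt A unpairable),
    mid-loop for a neutral one (ref A, alt C).
    """
    L, sl, ll = cfg.window_len, cfg.stem_len, cfg.loop_len
    centre = (L + 1) // 2
    hp_len = 2 * sl + ll

    stem5 = list(rng.choice(["G", "C"], size=sl))
    loop = ["A"] * ll
    if disruptive:
        snv_in_hp = sl // 2  # 0-based offset within the hairpin
        stem5[snv_in_hp] = "G"
    else:
        snv_in_hp = sl + ll // 2
    hp_start = centre - snv_in_hp  # 1-based start of the hairpin
    if hp_start < 1 or hp_start + hp_len - 1 > L:
        raise ValueError(
            f"hairpin geometry (stem {sl}, loop {ll}) does not fit a "
            f"window of length {L}"
        )
    stem3 = [_COMPLEMENT[b] for b in reversed(stem5)]
    hairpin = stem5 + loop + stem3

    n_left = hp_start - 1
    n_right = L - (hp_start + hp_len - 1)
    left = rng.choice(["A", "C"], size=n_left)
    right = rng.choice(["A", "C"], size=n_right)
    ref = "".join(left) + "".join(hairpin) + "".join(right)
    assert len(ref) == L

    if disruptive:
        ref_allele, alt_allele = "G", "A"
    else:
        ref_allele, alt_allele = "A", "C"
    assert ref[centre - 1] == ref_allele
    alt = ref[:centre - 1] + alt_allele + ref[centre:]
    return HairpinWindow(ref, alt, centre, disruptive)


def _draw_pvalue(rng: np.random.Generator, cfg: SimConfig, diff_yes: bool) -> float:
    if diff_yes:
        return float(rng.beta(cfg.p_alpha_pos, cfg.p_beta_pos))
    return float(rng.beta(cfg.p_alpha_neg, cfg.p_beta_neg))


def _trio_config(
    rng: np.random.Generator,
    ref: str,
    alt: str,
    label: str,
    symmetric: bool,
    eligible: bool,
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Genotypes and pairwise diff calls realising the requested category.

    Two genotype layouts are used: the validation-eligible one (mother
    ref/ref, father alt/alt, child het — all three comparisons
    applicable) and a two-comparison layout (mother ref/ref, father and
    child het).
    """
    r2, a2, het = ref + ref, alt + alt, ref + alt
    if eligible:
        gts = {"mother": r2, "father": a2, "child": het}
        applicable = list(PAIR_KEYS)
    else:
        gts = {"mother": r2, "father": het, "child": het}
        applicable = ["mother-father", "mother-child"]

    diffs = {k: "not_applicable" for k in PAIR_KEYS}
    if label == "riboSNitch":
        if symmetric:
            calls = ["yes"] * len(applicable)
        else:
            # asymmetric: at least one yes and one no
            n_yes = int(rng.integers(1, len(applicable)))
            calls = ["yes"] * n_yes + ["no"] * (len(applicable) - n_yes)
            rng.shuffle(calls)
    else:
        calls = ["no"] * len(applicable)
    for k, c in zip(applicable, calls):
        diffs[k] = c
    return gts, diffs


@dataclass
class SimulatedDataset:
    """Generator output plus the ground truth it realised."""

    config: SimConfig
    transcripts: Dict[str, RnaSequence]
    snvs: List[SNVRecord]
    # per snv_id: intended label, intended category, whether the SNV is
    # structurally disruptive (False for environmental riboSNitches)
    truth: Dict[str, Dict] = field(default_factory=dict)


def simulate_trio_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate transcripts and an SNV table realising *cfg*.

    Each SNV gets its own transcript, exactly one window long with the
    SNV at the centre, so window extraction reproduces the generated
    window with zero exclusions.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts: Dict[str, RnaSequence] = {}
    snvs: List[SNVRecord] = []
    truth: Dict[str, Dict] = {}

    specs = [("riboSNitch", i) for i in range(cfg.n_ribosnitch)]
    specs += [("non-riboSNitch", i) for i in range(cfg.n_non)]

    for idx, (label, _) in enumerate(specs):
        snv_id = f"snv{idx:05d}"
        tx_id = f"TX{idx:05d}"
        if label == "riboSNitch":
            symmetric = bool(rng.random() < cfg.frac_symmetric)
            eligible = bool(rng.random() < cfg.frac_validated_eligible)
            probed = bool(rng.random() < cfg.frac_probed)
            environmental = bool(rng.random() < cfg.noise_frac)
            disruptive = not environmental
        else:
            symmetric = False
            eligible = bool(rng.random() < cfg.frac_validated_eligible)
            probed = False
            environmental = False
            disruptive = False

        hp = make_hairpin_window(cfg, rng, disruptive=disruptive)
        gts, diffs = _trio_config(
            rng, hp.ref_allele, hp.alt_allele, label, symmetric, eligible
        )
        pvals = {
            k: (_draw_pvalue(rng, cfg, v == "yes") if v != "not_applicable" else None)
            for k, v in diffs.items()
        }
        snv = SNVRecord(
            snv_id=snv_id,
            transcript_id=tx_id,
            position=hp.snv_offset,
            ref_allele=hp.ref_allele,
            alt_allele=hp.alt_allele,
            genotypes=gts,
            pairwise_diff=diffs,
            fdr_p=pvals,
            allele_specific_validated=(label == "riboSNitch" and eligible),
            probed=probed,
        )
        transcripts[tx_id] = RnaSequence(tx_id, hp.ref_bases)
        snvs.append(snv)
        truth[snv_id] = {
            "label": label,
            "category": (
                ("symmetric" if symmetric else "asymmetric")
                if label == "riboSNitch"
                else "non-riboSNitch"
            ),
            "disruptive": disruptive,
            "validated": label == "riboSNitch" and eligible,
            "probed": probed,
        }
    return SimulatedDataset(config=cfg, transcripts=transcripts, snvs=snvs,
                            truth=truth)
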