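"""Benchmark window construction from transcripts and trio SNV tables.

Turns transcript sequences plus single-nucleotide variants genotyped in a
mother/father/child trio into the benchmark's non-redundant, category-labelled
set of allele sequence pairs:

* extract a window of 50 bases either side of each SNV (101 bases total),
  excluding SNVs with fewer than 50 nucleotides between them and the
  transcription start site;
* classify each SNV from its pairwise structure-difference calls as a
  symmetric riboSNitch (every genotype difference shows a structure
  difference), an asymmetric riboSNitch (only some do), or a
  non-riboSNitch (none do);
* check allele-specific-validation eligibility (parents homozygous
  different, child heterozygous);
* collapse identical windows arising from multiple isoforms into one
  non-redundant entry, a single riboSNitch source being enough to label
  the merged window a riboSNitch and categories accumulating as unions.

Coordinates are 1-based inclusive in every file format and public field;
slicing into Python strings is the only place 0-based arithmetic appears.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .fold import RnaSequence

__all__ = [
    "SNVRecord",
    "SequenceWindow",
    "WindowExclusion",
    "extract_window",
    "deduplicate",
    "assign_category",
    "flag_validated",
    "build_windows",
    "DEFAULT_FLANK",
]

logger = logging.getLogger("ribobench")

DEFAULT_FLANK = 50

PAIR_KEYS = ("mother-father", "mother-child", "father-child")
_PAIR_MEMBERS = {
    "mother-father": ("mother", "father"),
    "mother-child": ("mother", "child"),
    "father-child": ("father", "child"),
}

RIBOSNITCH = "riboSNitch"
NON_RIBOSNITCH = "non-riboSNitch"


def _norm_genotype(gt: str) -> str:
    """Normalise a diploid genotype to a sorted two-letter string."""
    gt = gt.upper().replace("T", "U").replace("/", "").replace("|", "")
    if len(gt) != 2:
        raise ValueError(f"genotype {gt!r} is not diploid")
    return "".join(sorted(gt))


@dataclass
class SNVRecord:
    """One SNV tested in one transcript, with trio PARS comparison results.

    ``pairwise_diff`` holds, per trio comparison, whether the PARS profiles
    around the SNV differed significantly ("yes"/"no"), or
    "not_applicable" when the two genotypes are identical and no
    comparison is possible.  ``fdr_p`` holds the FDR-adjusted P-value of
    each applicable comparison.
    """

    snv_id: str
    transcript_id: str
    position: int  # 1-based offset in the transcript
    ref_allele: str
    alt_allele: str
    genotypes: Mapping[str, str]  # mother/father/child -> diploid genotype
    pairwise_diff: Mapping[str, str]  # pair key -> yes/no/not_applicable
    fdr_p: Mapping[str, Optional[float]] = field(default_factory=dict)
    allele_specific_validated: bool = False
    probed: bool = False

    def __post_init__(self):
        self.ref_allele = self.ref_allele.upper().replace("T", "U")
        self.alt_allele = self.alt_allele.upper().replace("T", "U")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snv_id}: ref and alt alleles are identical")
        self.genotypes = {k: _norm_genotype(v) for k, v in self.genotypes.items()}
        missing = {"mother", "father", "child"} - set(self.genotypes)
        if missing:
            raise ValueError(f"{self.snv_id}: missing genotypes for {sorted(missing)}")
        pd = {}
        for key in PAIR_KEYS:
            v = str(self.pairwise_diff.get(key, "not_applicable")).lower()
            if v not in ("yes", "no", "not_applicable"):
                raise ValueError(f"{self.snv_id}: bad pairwise_diff {v!r} for {key}")
            a, b = _PAIR_MEMBERS[key]
            same_gt = self.genotypes[a] == self.genotypes[b]
            if same_gt and v != "not_applicable":
                raise ValueError(
                    f"{self.snv_id}: comparison {key} has identical genotypes "
                    f"but diff={v!r} (must be not_applicable)"
                )
            if not same_gt and v == "not_applicable":
                raise ValueError(
                    f"{self.snv_id}: comparison {key} has different genotypes "
                    "but is marked not_applicable"
                )
            pd[key] = v
        self.pairwise_diff = pd
        fp = {}
        for key in PAIR_KEYS:
            p = self.fdr_p.get(key)
            if pd[key] != "not_applicable":
                if p is None:
                    raise ValueError(
                        f"{self.snv_id}: applicable comparison {key} lacks an "
                        "FDR-adjusted P-value"
                    )
                p = float(p)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{self.snv_id}: P-value {p} outside [0,1]")
            fp[key] = None if pd[key] == "not_applicable" else float(p)
        self.fdr_p = fp

    def applicable_pvalues(self) -> List[float]:
        return [p for p in self.fdr_p.values() if p is not None]

    def mean_fdr_p(self) -> float:
        """Average FDR-adjusted P over the applicable trio comparisons."""
        ps = self.applicable_pvalues()
        if not ps:
            raise ValueError(f"{self.snv_id}: no applicable comparisons")
        return sum(ps) / len(ps)


@dataclass
class SequenceWindow:
    """An SNV-centred window carrying both allele sequences.

    ``snv_offset`` is the 1-based position of the SNV within the window.
    The two allele sequences have equal length and differ exactly there.
    """

    window_id: str
    ref_seq: RnaSequence
    alt_seq: RnaSequence
    snv_offset: int
    source_snvs: List[str] = field(default_factory=list)
    label: str = NON_RIBOSNITCH
    categories: Set[str] = field(default_factory=set)
    truncated_3prime: bool = False
    mean_fdr_p: Optional[float] = None

    def __post_init__(self):
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError(f"{self.window_id}: allele sequences differ in length")
        diffs = [
            k + 1
            for k in range(len(self.ref_seq))
            if self.ref_seq.bases[k] != self.alt_seq.bases[k]
        ]
        if diffs != [self.snv_offset]:
            raise ValueError(
                f"{self.window_id}: alleles must differ exactly at snv_offset "
                f"{self.snv_offset}, found differences at {diffs}"
            )
        if self.label not in (RIBOSNITCH, NON_RIBOSNITCH):
            raise ValueError(f"{self.window_id}: bad label {self.label!r}")
        bad = set(self.categories) - {"symmetric", "asymmetric", "validated", "probed"}
        if bad:
            raise ValueError(f"{self.window_id}: unknown categories {sorted(bad)}")

    def key(self) -> Tuple[str, str, int]:
        """Redundancy key: identical (ref, alt, offset) windows are one entry."""
        return (self.ref_seq.bases, self.alt_seq.bases, self.snv_offset)


@dataclass
class WindowExclusion:
    """Record of an SNV excluded from window extraction, with the reason."""

    snv_id: str
    reason: str


def extract_window(
    transcript_seq: RnaSequence,
    snv: SNVRecord,
    flank: int = DEFAULT_FLANK,
):
    """Cut the window of *flank* bases either side of the SNV.

    Returns a :class:`SequenceWindow` (of length ``2*flank + 1`` when the
    transcript allows) or a :class:`WindowExclusion` when fewer than
    *flank* nucleotides separate the SNV from the transcription start
    site.  Windows truncated by the transcript 3' end are kept but
    flagged ``truncated_3prime``.  A reference-allele mismatch against the
    transcript is a hard error.
    """
    n = len(transcript_seq)
    pos = snv.position
    if not 1 <= pos <= n:
        raise ValueError(
            f"{snv.snv_id}: position {pos} outside transcript "
            f"{transcript_seq.id} (length {n})"
        )
    tbase = transcript_seq.base(pos)
    if tbase != snv.ref_allele:
        raise ValueError(
            f"{snv.snv_id}: ref allele {snv.ref_allele} does not match "
            f"transcript base {tbase} at position {pos}"
        )
    if pos - 1 < flank:
        return WindowExclusion(
            snv.snv_id,
            f"fewer than {flank} nucleotides between the SNV and the "
            "transcription start site",
        )
    start = pos - flank  # 1-based
    end = min(pos + flank, n)
    ref_bases = transcript_seq.bases[start - 1:end]
    offset = pos - start + 1
    alt_bases = ref_bases[:offset - 1] + snv.alt_allele + ref_bases[offset:]
    wid = f"{snv.transcript_id}:{pos}{snv.ref_allele}>{snv.alt_allele}"
    return SequenceWindow(
        window_id=wid,
        ref_seq=RnaSequence(wid + "|ref", ref_bases),
        alt_seq=RnaSequence(wid + "|alt", alt_bases),
        snv_offset=offset,
        source_snvs=[snv.snv_id],
        truncated_3prime=(pos + flank > n),
    )


def assign_category(snv: SNVRecord) -> str:
    """Classify an SNV from its applicable trio comparisons.

    symmetric: every applicable comparison shows a structure difference;
    asymmetric: some do and some do not; non-riboSNitch: none do.  A trio
    with all-identical genotypes has no applicable comparison and raises.
    """
    calls = [v for v in snv.pairwise_diff.values() if v != "not_applicable"]
    if not calls:
        raise ValueError(
            f"{snv.snv_id}: all trio genotypes identical, no comparison possible"
        )
    n_yes = sum(1 for v in calls if v == "yes")
    if n_yes == len(calls):
        return "symmetric"
    if n_yes == 0:
        return NON_RIBOSNITCH
    return "asymmetric"


def validated_eligible(snv: SNVRecord) -> bool:
    """Allele-specific mapping requires homozygous-different parents and a
    heterozygous child."""
    m, f, c = (snv.genotypes[k] for k in ("mother", "father", "child"))
    hom = lambda g: g[0] == g[1]
    return hom(m) and hom(f) and m != f and c[0] != c[1]


def flag_validated(snv: SNVRecord) -> Tuple[bool, bool]:
    """Return (validated flag, consistent).

    The flag itself comes from the input record — it encodes an external
    allele-specific read-mapping result that the toolkit does not
    recompute.  Eligibility (parents homozygous different, child
    heterozygous) is checked for consistency; a flag set on an ineligible
    genotype configuration is kept but reported inconsistent with a
    warning.
    """
    if not snv.allele_specific_validated:
        return False, True
    if validated_eligible(snv):
        return True, True
    msg = (
        f"{snv.snv_id}: validated flag set but genotype configuration is not "
        "eligible for allele-specific mapping (kept, marked inconsistent)"
    )
    logger.warning(msg)
    warnings.warn(msg, stacklevel=2)
    return True, False


def snv_categories(snv: SNVRecord) -> Tuple[str, Set[str]]:
    """(label, categories) for one SNV record."""
    cat = assign_category(snv)
    if cat == NON_RIBOSNITCH:
        return NON_RIBOSNITCH, set()
    cats = {cat}
    validated, _ = flag_validated(snv)
    if validated:
        cats.add("validated")
    if snv.probed:
        cats.add("probed")
    return RIBOSNITCH, cats


def deduplicate(windows: Sequence[SequenceWindow]) -> List[SequenceWindow]:
    """Merge windows with identical (ref, alt, offset) into one entry.

    One riboSNitch source suffices to label the merged window a
    riboSNitch; categories are unioned; source SNV lists concatenate in
    input order.  The merged mean FDR P-value is the mean of the sources'
    means.  Idempotent, and label outcomes do not depend on input order.
    """
    merged: Dict[Tuple[str, str, int], SequenceWindow] = {}
    order: List[Tuple[str, str, int]] = []
    for w in windows:
        k = w.key()
        if k not in merged:
            merged[k] = replace(
                w,
                source_snvs=list(w.source_snvs),
                categories=set(w.categories),
            )
            order.append(k)
        else:
            m = merged[k]
            m.source_snvs.extend(w.source_snvs)
            if w.label == RIBOSNITCH:
                m.label = RIBOSNITCH
            m.categories |= w.categories
            m.truncated_3prime = m.truncated_3prime or w.truncated_3prime
            ps = [p for p in (m.mean_fdr_p, w.mean_fdr_p) if p is not None]
            m.mean_fdr_p = sum(ps) / len(ps) if ps else None
            logger.info(
                "deduplicate: merged %s into %s", w.window_id, m.window_id
            )
    return [merged[k] for k in order]


def build_windows(
    transcripts: Mapping[str, RnaSequence],
    snvs: Sequence[SNVRecord],
    flank: int = DEFAULT_FLANK,
    drop_truncated: bool = False,
) -> Tuple[List[SequenceWindow], List[WindowExclusion]]:
    """Full benchmark-set construction: extract, label, deduplicate.

    Returns the non-redundant labelled windows and the exclusion records.
    """
    out: List[SequenceWindow] = []
    excluded: List[WindowExclusion] = []
    for snv in snvs:
        if snv.transcript_id not in transcripts:
            raise KeyError(f"{snv.snv_id}: unknown transcript {snv.transcript_id}")
        res = extract_window(transcripts[snv.transcript_id], snv, flank=flank)
        if isinstance(res, WindowExclusion):
            excluded.append(res)
            continue
        if res.truncated_3prime and drop_truncated:
            excluded.append(
                WindowExclusion(snv.snv_id, "window truncated by transcript 3' end")
            )
            continue
        label, cats = snv_categories(snv)
        res.label = label
        res.categories = cats
        res.mean_fdr_p = snv.mean_fdr_p()
        out.append(res)
    return deduplicate(out), excluded
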