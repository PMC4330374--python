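"""File formats and configuration.

Everything on disk is plain text: FASTA for sequences (via Biopython),
TSV with '#'-prefixed metadata lines for tables, YAML for configuration.
Floats are written with 12 significant digits and every writer/reader
pair round-trips exactly at that precision.  Missing values in tables are
".".
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bench import BenchmarkRow
from .fold import BPPM, EnergyModel, RnaSequence, SecondaryStructure
from .simulate import SimConfig, SimulatedDataset
from .windows import PAIR_KEYS, SNVRecord, SequenceWindow

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_snv_table",
    "write_snv_table",
    "read_bppm",
    "write_bppm",
    "read_dot_bracket",
    "write_dot_bracket",
    "write_windows",
    "read_windows",
    "write_scores",
    "read_scores",
    "write_report",
    "write_roc_points",
    "load_model_config",
    "load_sim_config",
    "read_supplementary_sequences",
    "write_simulated_dataset",
]

logger = logging.getLogger("ribobench")

FLOAT_FMT = "{:.12g}"
MISSING = "."

_SNV_COLUMNS = [
    "snv_id", "transcript_id", "pos", "ref", "alt",
    "gt_mother", "gt_father", "gt_child",
    "diff_mf", "diff_mc", "diff_fc",
    "p_mf", "p_mc", "p_fc",
    "validated", "probed",
]
_PAIR_SHORT = {"mother-father": "mf", "mother-child": "mc", "father-child": "fc"}


def _fmt(x: Optional[float]) -> str:
    return MISSING if x is None else FLOAT_FMT.format(x)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> Dict[str, RnaSequence]:
    """FASTA file -> {record id: RnaSequence} (T normalised to U)."""
    out: Dict[str, RnaSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = RnaSequence(rec.id, str(rec.seq))
    return out


def write_fasta(path: Union[str, Path], seqs: Iterable[RnaSequence]) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SNV tables
# ---------------------------------------------------------------------------

def write_snv_table(path: Union[str, Path], snvs: Sequence[SNVRecord],
                    header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(_SNV_COLUMNS) + "\n")
        for s in snvs:
            row = [
                s.snv_id, s.transcript_id, str(s.position),
                s.ref_allele, s.alt_allele,
                s.genotypes["mother"], s.genotypes["father"], s.genotypes["child"],
            ]
            for key in PAIR_KEYS:
                v = s.pairwise_diff[key]
                row.append(MISSING if v == "not_applicable" else v)
            for key in PAIR_KEYS:
                row.append(_fmt(s.fdr_p[key]))
            row.append("yes" if s.allele_specific_validated else "no")
            row.append("yes" if s.probed else "no")
            fh.write("\t".join(row) + "\n")


def read_snv_table(path: Union[str, Path]) -> List[SNVRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing_cols = set(_SNV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"SNV table {path} lacks columns {sorted(missing_cols)}")
    out: List[SNVRecord] = []
    for _, r in df.iterrows():
        diffs, ps = {}, {}
        for key in PAIR_KEYS:
            short = _PAIR_SHORT[key]
            d = r[f"diff_{short}"]
            diffs[key] = "not_applicable" if d == MISSING else d
            p = r[f"p_{short}"]
            ps[key] = None if p == MISSING else float(p)
        out.append(SNVRecord(
            snv_id=r["snv_id"],
            transcript_id=r["transcript_id"],
            position=int(r["pos"]),
            ref_allele=r["ref"],
            alt_allele=r["alt"],
            genotypes={"mother": r["gt_mother"], "father": r["gt_father"],
                       "child": r["gt_child"]},
            pairwise_diff=diffs,
            fdr_p=ps,
            allele_specific_validated=r["validated"].lower() == "yes",
            probed=r["probed"].lower() == "yes",
        ))
    return out


# ---------------------------------------------------------------------------
# BPPM exchange format: `# length=n` comment, then `i  j  prob` (1-based)
# ---------------------------------------------------------------------------

def write_bppm(path: Union[str, Path], bppm: BPPM) -> None:
    with open(path, "w") as fh:
        fh.write(f"# length={bppm.length}\n")
        fh.write("i\tj\tprob\n")
        for (i, j) in sorted(bppm.probs):
            fh.write(f"{i}\t{j}\t{FLOAT_FMT.format(bppm.probs[(i, j)])}\n")


def read_bppm(path: Union[str, Path]) -> BPPM:
    length = None
    probs: Dict[Tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("length="):
                    length = int(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if parts == ["i", "j", "prob"]:
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            i, j, p = int(parts[0]), int(parts[1]), float(parts[2])
            probs[(i, j)] = p
    if length is None:
        raise ValueError(f"{path}: missing '# length=n' line")
    return BPPM(length, probs)


# ---------------------------------------------------------------------------
# Dot-bracket text: one structure per line, optional energy after a tab
# ---------------------------------------------------------------------------

def write_dot_bracket(path: Union[str, Path],
                      structures: Iterable[SecondaryStructure]) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s.dot_bracket}\t{FLOAT_FMT.format(s.energy)}\n")


def read_dot_bracket(path: Union[str, Path]) -> List[SecondaryStructure]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                db, e = line.split("\t", 1)
                out.append(SecondaryStructure.from_dot_bracket(db, float(e)))
            else:
                out.append(SecondaryStructure.from_dot_bracket(line))
    return out


# ---------------------------------------------------------------------------
# Windows: FASTA (two records per window) + metadata TSV
# ---------------------------------------------------------------------------

def write_windows(fasta_path: Union[str, Path], meta_path: Union[str, Path],
                  windows: Sequence[SequenceWindow]) -> None:
    seqs: List[RnaSequence] = []
    for w in windows:
        seqs.append(RnaSequence(f"{w.window_id}|ref", w.ref_seq.bases))
        seqs.append(RnaSequence(f"{w.window_id}|alt", w.alt_seq.bases))
    write_fasta(fasta_path, seqs)
    with open(meta_path, "w") as fh:
        fh.write("window_id\tsnv_offset\tlabel\tcategories\tsource_snvs\t"
                 "truncated_3prime\tmean_fdr_p\n")
        for w in windows:
            cats = ",".join(sorted(w.categories)) or MISSING
            srcs = ",".join(w.source_snvs) or MISSING
            fh.write(
                f"{w.window_id}\t{w.snv_offset}\t{w.label}\t{cats}\t{srcs}\t"
                f"{'yes' if w.truncated_3prime else 'no'}\t{_fmt(w.mean_fdr_p)}\n"
            )


def read_windows(fasta_path: Union[str, Path],
                 meta_path: Union[str, Path]) -> List[SequenceWindow]:
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    out: List[SequenceWindow] = []
    for _, r in df.iterrows():
        wid = r["window_id"]
        try:
            ref = seqs[f"{wid}|ref"]
            alt = seqs[f"{wid}|alt"]
        except KeyError as e:
            raise ValueError(f"window {wid}: missing FASTA record {e}") from None
        out.append(SequenceWindow(
            window_id=wid,
            ref_seq=ref,
            alt_seq=alt,
            snv_offset=int(r["snv_offset"]),
            source_snvs=[] if r["source_snvs"] == MISSING
            else r["source_snvs"].split(","),
            label=r["label"],
            categories=set() if r["categories"] == MISSING
            else set(r["categories"].split(",")),
            truncated_3prime=r.get("truncated_3prime", "no") == "yes",
            mean_fdr_p=None if r.get("mean_fdr_p", MISSING) == MISSING
            else float(r["mean_fdr_p"]),
        ))
    return out


# ---------------------------------------------------------------------------
# Scores and reports
# ---------------------------------------------------------------------------

def write_scores(path: Union[str, Path], rows: Sequence[Mapping]) -> None:
    """Rows need window_id, metric, score, label, categories."""
    with open(path, "w") as fh:
        fh.write("window_id\tmetric\tscore\tlabel\tcategories\n")
        for r in rows:
            cats = r.get("categories") or MISSING
            if isinstance(cats, (set, frozenset, list, tuple)):
                cats = ",".join(sorted(cats)) or MISSING
            fh.write(
                f"{r['window_id']}\t{r['metric']}\t"
                f"{FLOAT_FMT.format(r['score'])}\t{r['label']}\t{cats}\n"
            )


def read_scores(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    df["score"] = df["score"].astype(float)
    return df


def write_report(path: Union[str, Path], rows: Sequence[BenchmarkRow]) -> None:
    cols = ["metric", "category", "n_pos", "n_neg", "auc", "ci_low", "ci_high",
            "best_threshold", "best_sens", "best_spec"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            vals = [r.metric, r.category, str(r.n_pos), str(r.n_neg),
                    _fmt(r.auc), _fmt(r.ci_low), _fmt(r.ci_high),
                    _fmt(r.best_threshold), _fmt(r.best_sens), _fmt(r.best_spec)]
            fh.write("\t".join(vals) + "\n")


def write_roc_points(directory: Union[str, Path],
                     rows: Sequence[BenchmarkRow]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r in rows:
        if not r.roc_points:
            continue
        slug = f"{r.metric}_{r.category}".replace("%", "pct")
        slug = "".join(c if c.isalnum() or c in "._-" else "_" for c in slug)
        with open(directory / f"{slug}.tsv", "w") as fh:
            fh.write("threshold\tsensitivity\tspecificity\n")
            for t, sens, spec in r.roc_points:
                fh.write(f"{FLOAT_FMT.format(t)}\t{FLOAT_FMT.format(sens)}\t"
                         f"{FLOAT_FMT.format(spec)}\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_MODEL_KEYS = {"pair_energies", "stack_energies", "min_hairpin_loop",
               "temperature_kT"}


def _checked_yaml(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return data


def load_model_config(path: Optional[Union[str, Path]]) -> EnergyModel:
    """Energy model from a YAML file; None -> defaults.

    Recognised keys: pair_energies, stack_energies, min_hairpin_loop,
    temperature_kT.  Unknown keys are rejected.
    """
    if path is None:
        return EnergyModel()
    data = _checked_yaml(path)
    unknown = set(data) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown model keys {sorted(unknown)}")
    kwargs = {}
    if "pair_energies" in data:
        kwargs["pair_energies"] = dict(data["pair_energies"])
    if "stack_energies" in data and data["stack_energies"] is not None:
        kwargs["stack_energies"] = dict(data["stack_energies"])
    if "min_hairpin_loop" in data:
        kwargs["min_hairpin_loop"] = int(data["min_hairpin_loop"])
    if "temperature_kT" in data:
        kwargs["temperature_kT"] = float(data["temperature_kT"])
    return EnergyModel(**kwargs)


def load_sim_config(path: Union[str, Path]) -> SimConfig:
    """Simulation config from YAML; unknown keys are rejected."""
    data = _checked_yaml(path)
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown simulation keys {sorted(unknown)}")
    return SimConfig(**data)


# ---------------------------------------------------------------------------
# Supplementary-style labelled sequence files
# ---------------------------------------------------------------------------

def read_supplementary_sequences(
    path: Union[str, Path],
    label: str = "riboSNitch",
    category: Optional[str] = None,
    snv_offset: Optional[int] = None,
) -> List[Tuple[str, RnaSequence]]:
    """Read a labelled benchmark sequence text file.

    Two dialects are auto-detected: FASTA (headers may carry a category
    token after the id, e.g. ``>seq1 symmetric``) and plain
    one-sequence-per-line text.  Returns (category, sequence) tuples;
    duplicate sequences are collapsed with a warning.  Unparseable lines
    are reported with their line numbers.
    """
    path = Path(path)
    entries: List[Tuple[str, RnaSequence]] = []
    text = path.read_text()
    lines = text.splitlines()
    nonblank = [ln for ln in lines if ln.strip()]
    if not nonblank:
        warnings.warn(f"{path}: empty sequence file", stacklevel=2)
        return []
    if nonblank[0].lstrip().startswith(">"):
        # FASTA dialect
        rec_id, rec_cat, chunks, lineno0 = None, None, [], 0

        def flush():
            if rec_id is None:
                return
            bases = "".join(chunks)
            try:
                entries.append((rec_cat or category or "all",
                                RnaSequence(rec_id, bases)))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno0}: {e}") from None

        for lineno, ln in enumerate(lines, start=1):
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith(">"):
                flush()
                fields = ln[1:].split()
                if not fields:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                rec_id = fields[0]
                rec_cat = fields[1] if len(fields) > 1 else None
                chunks, lineno0 = [], lineno
            else:
                chunks.append(ln)
        flush()
    else:
        for lineno, ln in enumerate(lines, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            try:
                entries.append((category or "all",
                                RnaSequence(f"{path.stem}:{lineno}", ln)))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None

    seen: Dict[str, Tuple[str, RnaSequence]] = {}
    dupes = 0
    for cat, seq in entries:
        if seq.bases in seen:
            dupes += 1
        else:
            seen[seq.bases] = (cat, seq)
    if dupes:
        warnings.warn(
            f"{path}: collapsed {dupes} duplicate sequences "
            f"({len(seen)} unique)",
            stacklevel=2,
        )
    return list(seen.values())


def write_simulated_dataset(dataset: SimulatedDataset,
                            out_dir: Union[str, Path]) -> Tuple[Path, Path]:
    """Write a simulated dataset as (SNV table TSV, transcript FASTA)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snv_path = out_dir / "snvs.tsv"
    fasta_path = out_dir / "transcripts.fasta"
    write_snv_table(
        snv_path, dataset.snvs,
        header_comment=f"simulated trio-PARS dataset, seed={dataset.config.seed}",
    )
    write_fasta(fasta_path, dataset.transcripts.values())
    return snv_path, fasta_path
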