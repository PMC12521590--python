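"""Readers/writers for the external formats the pipeline touches.

Formats handled: FASTA protein databases (UniProt ``sp|ACC|NAME`` and
bare-accession header dialects), tab-separated peptide reports in three
dialects (``pd``, ``fragpipe``, ``generic``), sample design tables, signal
peptide annotation tables, cleavage-site databases, GMT gene-set files and
the YAML/JSON pipeline configuration.

Coordinate convention: residue positions are 1-based inclusive throughout;
a cleavage site is written P1|P1' with P1 the residue index immediately
N-terminal to the scissile bond.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("terminome_miner")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL = set(AMINO_ACIDS) | {"X"}
#: residues silently mapped to 'X'; anything else is mapped with a warning
_TOLERATED_NONSTANDARD = {"U", "B", "Z"}
BOUNDARY = "-"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """A protein sequence with optional signal-peptide annotation.

    ``signal_end`` is the 1-based index of the last signal-peptide residue;
    the mature protein then starts at ``signal_end + 1``.
    """

    accession: str
    sequence: str
    signal_end: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _CANONICAL
        if bad:
            raise ValueError(f"{self.accession}: non-canonical residues {sorted(bad)}")
        if self.signal_end is not None and not (1 <= self.signal_end < len(self.sequence)):
            raise ValueError(
                f"{self.accession}: signal_end {self.signal_end} outside "
                f"[1, {len(self.sequence) - 1}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """1-based residue access; '-' outside the protein."""
        if 1 <= pos <= len(self.sequence):
            return self.sequence[pos - 1]
        return BOUNDARY


@dataclass
class SampleDesign:
    """Two-group sample design (e.g. CASE vs CONTROL)."""

    samples: list[str]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group: {missing}")
        groups = sorted(set(self.group_of[s] for s in self.samples))
        if len(groups) != 2:
            raise ValueError(f"design must have exactly 2 groups, found {groups}")
        self._groups = groups

    @property
    def groups(self) -> tuple[str, str]:
        return tuple(self._groups)  # type: ignore[return-value]

    def members(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.members(g)) for g in self.groups}


@dataclass
class PeptideReportRow:
    """One row of a peptide-level search-engine export."""

    peptide: str
    proteins: tuple[str, ...]
    start: int | None
    end: int | None
    prev_aa: str | None
    next_aa: str | None
    intensities: dict[str, float]  # sample -> intensity; missing = NaN
    fdr: float = 0.0

    @property
    def needs_mapping(self) -> bool:
        return self.start is None or self.end is None


@dataclass
class CleavageSiteRecord:
    """A curated cleavage site: protease cuts ``accession`` after residue P1."""

    accession: str
    p1_position: int
    protease: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.p1_position < 1:
            raise ValueError(f"p1_position must be >= 1, got {self.p1_position}")


@dataclass
class PipelineConfig:
    """All thresholds the analysis applies, with their study defaults."""

    lfc_threshold: float = 0.57
    alpha_p: float = 0.05
    alpha_q: float = 0.05
    peptide_fdr_max: float = 0.01
    protein_fdr_max: float = 0.05
    min_unique_peptides: int = 1
    min_presence: int = 3
    exclusivity_fraction: float = 0.50
    specificity_fraction: float = 0.75
    window_half_width: int = 5
    seed: int = 0
    dialect: str = "generic"
    zero_is_missing: bool = True
    proline_rule: bool = True
    allow_non_tryptic: bool = False
    storey_lambda: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha_p", "alpha_q", "peptide_fdr_max", "protein_fdr_max",
                     "exclusivity_fraction", "specificity_fraction", "storey_lambda"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.min_presence < 0 or self.min_unique_peptides < 0:
            raise ValueError("count thresholds must be >= 0")
        if self.window_half_width < 1:
            raise ValueError("window_half_width must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_UNIPROT_HEADER = re.compile(r"^(sp|tr)\|([^|]+)\|")


def _accession_from_header(header: str) -> str:
    first = header.split()[0]
    m = _UNIPROT_HEADER.match(first)
    return m.group(2) if m else first


def _clean_sequence(accession: str, raw: str) -> str:
    seq = raw.upper()
    if seq != raw:
        logger.warning("%s: lowercase residues uppercased", accession)
    out = []
    warned: set[str] = set()
    for ch in seq:
        if ch in _CANONICAL:
            out.append(ch)
        elif ch in _TOLERATED_NONSTANDARD:
            out.append("X")
        else:
            if ch not in warned:
                logger.warning("%s: residue %r mapped to 'X'", accession, ch)
                warned.add(ch)
            out.append("X")
    return "".join(out)


def read_fasta(path: str | Path, signal_ends: Mapping[str, int] | None = None
               ) -> list[ProteinRecord]:
    """Read a protein FASTA; raises on empty files and duplicate accessions."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(entry.description or entry.id)
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc}")
        seen.add(acc)
        seq = _clean_sequence(acc, str(entry.seq))
        signal_end = signal_ends.get(acc) if signal_ends else None
        records.append(ProteinRecord(acc, seq, signal_end, entry.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def read_signal_table(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["accession", "signal_end"], path)
    return dict(zip(df["accession"].astype(str), df["signal_end"].astype(int)))


def write_signal_table(signal_ends: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"accession": list(signal_ends), "signal_end": list(signal_ends.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide reports
# ---------------------------------------------------------------------------

#: per-dialect column names: (peptide, protein, start, end, prev, next, fdr)
_DIALECTS = {
    "generic": ("peptide", "protein", "start", "end", "prev_aa", "next_aa", "fdr"),
    "pd": ("Sequence", "Master Protein Accessions", "Position Start",
           "Position End", "Prev AA", "Next AA", "Percolator q-Value"),
    "fragpipe": ("Peptide", "Protein", "Protein Start", "Protein End",
                 "Prev AA", "Next AA", "Peptide q-Value"),
}
#: required at read time; coordinates/flanks may be absent (mapped later)
_REQUIRED_IDX = (0, 1)
_INTENSITY_SUFFIX = {"pd": "Abundance: ", "fragpipe": " Intensity", "generic": ""}


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_peptide_report(path: str | Path, dialect: str = "generic",
                        zero_is_missing: bool = True) -> list[PeptideReportRow]:
    """Parse a peptide export.

    Blank intensity cells are always missing; zeros are treated as missing by
    default (the usual not-observed convention) unless ``zero_is_missing`` is
    False.  Rows above the peptide-FDR threshold are retained here — filtering
    is the caller's decision.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    names = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, [names[i] for i in _REQUIRED_IDX], path)

    suffix = _INTENSITY_SUFFIX[dialect]
    meta_cols = set(names)
    if dialect == "pd":
        sample_cols = [c for c in df.columns if c.startswith(suffix)]
        sample_of = {c: c[len(suffix):] for c in sample_cols}
    elif dialect == "fragpipe":
        sample_cols = [c for c in df.columns if c.endswith(suffix)]
        sample_of = {c: c[: -len(suffix)] for c in sample_cols}
    else:
        sample_cols = [c for c in df.columns if c not in meta_cols]
        sample_of = {c: c for c in sample_cols}

    def parse_intensity(cell: str) -> float:
        if cell.strip() == "":
            return math.nan
        v = float(cell)
        if v == 0.0 and zero_is_missing:
            return math.nan
        if v < 0:
            raise ValueError(f"negative intensity {v!r} in {path}")
        return v

    def opt_int(cell: str) -> int | None:
        return int(float(cell)) if cell.strip() else None

    def opt_str(cell: str) -> str | None:
        return cell.strip() or None

    rows: list[PeptideReportRow] = []
    pep_c, prot_c, start_c, end_c, prev_c, next_c, fdr_c = names
    for _, r in df.iterrows():
        proteins = tuple(p.strip() for p in re.split(r"[;,]", r[prot_c]) if p.strip())
        rows.append(PeptideReportRow(
            peptide=r[pep_c].strip().upper(),
            proteins=proteins,
            start=opt_int(r[start_c]) if start_c in df.columns else None,
            end=opt_int(r[end_c]) if end_c in df.columns else None,
            prev_aa=opt_str(r[prev_c]) if prev_c in df.columns else None,
            next_aa=opt_str(r[next_c]) if next_c in df.columns else None,
            intensities={sample_of[c]: parse_intensity(r[c]) for c in sample_cols},
            fdr=float(r[fdr_c]) if fdr_c in df.columns and r[fdr_c].strip() else 0.0,
        ))
    return rows


def write_peptide_report(rows: Iterable[PeptideReportRow], path: str | Path,
                         samples: list[str]) -> None:
    """Write rows in the ``generic`` dialect (the round-trip format)."""
    records = []
    for row in rows:
        rec = {
            "peptide": row.peptide,
            "protein": ";".join(row.proteins),
            "start": "" if row.start is None else row.start,
            "end": "" if row.end is None else row.end,
            "prev_aa": row.prev_aa or "",
            "next_aa": row.next_aa or "",
            "fdr": row.fdr,
        }
        for s in samples:
            v = row.intensities.get(s, math.nan)
            rec[s] = "" if (v is None or (isinstance(v, float) and math.isnan(v))) else v
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design / cleavage DB / GMT
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample", "group"], path)
    samples = df["sample"].tolist()
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample ids")
    return SampleDesign(samples, dict(zip(df["sample"], df["group"])))


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame({
        "sample": design.samples,
        "group": [design.group_of[s] for s in design.samples],
    }).to_csv(path, sep="\t", index=False)


def check_design_covers(design: SampleDesign, samples: Iterable[str]) -> None:
    missing = sorted(set(samples) - set(design.samples))
    if missing:
        raise ValueError(f"samples in report absent from design: {missing}")


def read_cleavage_db(path: str | Path) -> list[CleavageSiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["accession", "p1_position", "protease"], path)
    evidence = df["evidence"] if "evidence" in df.columns else [""] * len(df)
    return [
        CleavageSiteRecord(acc, int(p1), protease, ev or "")
        for acc, p1, protease, ev in zip(
            df["accession"], df["p1_position"], df["protease"], evidence)
    ]


def write_cleavage_db(records: Iterable[CleavageSiteRecord], path: str | Path) -> None:
    pd.DataFrame.from_records(
        [(r.accession, r.p1_position, r.protease, r.evidence) for r in records],
        columns=["accession", "p1_position", "protease", "evidence"],
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one line per term — term, description, member, member, ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


# ---------------------------------------------------------------------------
# matrices and run summaries
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Feature x sample intensity matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature")


def write_json(obj: object, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def configure_logging(verbose: int = 0) -> None:
    level = logging.WARNING if verbose == 0 else logging.INFO if verbose == 1 else logging.DEBUG
    logging.basicConfig(stream=None, level=level,
                        format="%(levelname)s %(name)s: %(message)s")
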