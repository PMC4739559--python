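"""Input/output for the standard formats the pipeline touches.

FASTA alignments (via Biopython), tab-separated population metadata,
trajectory / table / network-edge TSVs, newick genealogies, and a JSON
run summary recording the seed and parameters of an invocation.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, SchemaError

__all__ = [
    "Alignment",
    "PopulationRecord",
    "read_fasta",
    "write_fasta",
    "read_population_table",
    "write_population_table",
    "read_trajectory",
    "write_trajectory",
    "write_network_edges",
    "write_table",
    "write_run_summary",
]

_VALID_CHARS = frozenset("ACGTN-")

# Range cells in field metadata use assorted dashes ("300-400", "290–321").
_RANGE_SPLIT = re.compile(r"[-‐‑‒–—―−]")


@dataclass(frozen=True)
class Alignment:
    """Aligned nucleotide sequences over the alphabet {A, C, G, T, N, -}.

    All sequences have equal length and ids are unique.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in number")
        if not self.seqs:
            raise FormatError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if len(self.seqs[0]) == 0:
            raise AlignmentError("zero-length sequences")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        for s in self.seqs:
            bad = set(s) - _VALID_CHARS
            if bad:
                raise FormatError(f"illegal characters in sequence: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """(n, L) array of single-character strings."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def subset(self, indices) -> "Alignment":
        return Alignment(
            ids=tuple(self.ids[i] for i in indices),
            seqs=tuple(self.seqs[i] for i in indices),
        )


@dataclass
class PopulationRecord:
    """One sampled population with its environmental covariates.

    Covariates may be missing (NaN). Precipitation given as a range in the
    source table is resolved to the arithmetic midpoint and flagged.
    """

    locality: str
    drainage: str
    n: int
    latitude: float = math.nan
    longitude: float = math.nan
    altitude: float = math.nan
    lake_area: float = math.nan
    basin_area: float = math.nan
    precipitation: float = math.nan
    precipitation_was_range: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population sample size must be >= 1")
        for name in ("altitude", "lake_area", "basin_area", "precipitation"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file; sequences are upper-cased.

    Raises FormatError on empty files or illegal characters, AlignmentError
    on ragged lengths.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return Alignment(ids=ids, seqs=seqs)


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(alignment.ids, alignment.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Population metadata
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("locality", "drainage", "n")
_FLOAT_COLUMNS = (
    "latitude",
    "longitude",
    "altitude",
    "lake_area",
    "basin_area",
    "precipitation",
)


def _parse_scalar_or_range(cell) -> tuple[float, bool]:
    """Parse a numeric cell that may hold a range like '300-400'.

    Returns (value, was_range); ranges resolve to the midpoint, blanks to NaN.
    """
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return math.nan, False
    text = str(cell).strip()
    if not text:
        return math.nan, False
    parts = [p for p in _RANGE_SPLIT.split(text) if p.strip()]
    if len(parts) == 2:
        lo, hi = (float(p) for p in parts)
        return (lo + hi) / 2.0, True
    return float(text), False


def read_population_table(path) -> list[PopulationRecord]:
    """Read a tab-separated population metadata table.

    Required columns: locality, drainage, n. Optional covariate columns:
    latitude, longitude, altitude, lake_area, basin_area, precipitation.
    Precipitation range cells ('a-b') resolve to the midpoint.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {
            "locality": row["locality"],
            "drainage": row["drainage"],
            "n": int(row["n"]),
        }
        for col in _FLOAT_COLUMNS:
            if col not in df.columns:
                continue
            value, was_range = _parse_scalar_or_range(row[col])
            kwargs[col] = value
            if col == "precipitation":
                kwargs["precipitation_was_range"] = was_range
        records.append(PopulationRecord(**kwargs))
    return records


def write_population_table(records: list[PopulationRecord], path) -> None:
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trajectories, tables, networks, run summaries
# ---------------------------------------------------------------------------

def write_trajectory(times_kya, values, path) -> None:
    """Write an effective-size trajectory as two-column TSV (time_kya, value).

    Times must be strictly increasing.
    """
    times_kya = np.asarray(times_kya, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_kya.ndim != 1 or times_kya.shape != values.shape:
        raise ValueError("times and values must be 1-D and equal length")
    if np.any(np.diff(times_kya) <= 0):
        raise ValueError("trajectory times must be strictly increasing")
    df = pd.DataFrame({"time_kya": times_kya, "value": values})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_trajectory(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if not {"time_kya", "value"} <= set(df.columns):
        raise SchemaError("trajectory TSV needs columns time_kya, value")
    return df["time_kya"].to_numpy(float), df["value"].to_numpy(float)


def write_network_edges(edges, path) -> None:
    """Edge-list TSV: node, node, steps, inferred_flag (either end inferred)."""
    df = pd.DataFrame(edges, columns=["node_a", "node_b", "steps", "inferred_flag"])
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, columns=None) -> None:
    """Write a result table as TSV with a fixed column order."""
    if columns is not None:
        df = df.loc[:, list(columns)]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_run_summary(path, *, seed, parameters: dict, outputs: dict | None = None) -> None:
    """Machine-readable JSON summary of one invocation."""
    payload = {"seed": seed, "parameters": parameters, "outputs": outputs or {}}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
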