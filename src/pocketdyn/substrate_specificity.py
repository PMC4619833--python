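"""Substrate tables and position-wise cleavage entropy.

Proteases recognise their substrates through sub-pocket interactions with the
residues flanking the scissile bond (Schechter–Berger nomenclature: substrate
positions P6…P1 on the non-prime side bind protease sub-pockets S6…S1).
Given a table of known cleavage sites, the specificity of each position is
quantified as the *cleavage entropy*: the Shannon entropy of the residue
frequencies at that position, normalised by ``log 20`` so that

* 0 means absolute specificity (a single residue type is ever observed), and
* 1 means no preference (all 20 residue types equally frequent).

Unknown residues (``"X"``) are excluded from both numerator and denominator,
and ``0·log 0`` is taken as 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "NONPRIME_POSITIONS",
    "SubstrateRecord",
    "SubstrateTable",
    "SpecificityProfile",
    "read_substrate_table",
    "positional_frequencies",
    "cleavage_entropy",
    "cleavage_entropy_profile",
]

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
UNKNOWN = "X"

#: Non-prime substrate positions, N- to C-terminal order (P6 farthest from the
#: scissile bond). Prime-side labels (P1', P2', …) are accepted by the parser
#: but excluded from the default entropy profile.
NONPRIME_POSITIONS: tuple[str, ...] = ("P6", "P5", "P4", "P3", "P2", "P1")
PRIME_POSITIONS: tuple[str, ...] = ("P1'", "P2'", "P3'", "P4'", "P5'", "P6'")
_KNOWN_POSITIONS = set(NONPRIME_POSITIONS) | set(PRIME_POSITIONS)


class UninformativePositionError(ValueError):
    """All residues at a position are unknown; no frequencies can be formed."""


@dataclass(frozen=True)
class SubstrateRecord:
    """One cleavage site: residue observed at each configured position."""

    substrate_id: str
    residues: Mapping[str, str]

    def __post_init__(self) -> None:
        for pos, aa in self.residues.items():
            if pos not in _KNOWN_POSITIONS:
                raise ValueError(f"unknown position label {pos!r}")
            if aa != UNKNOWN and aa not in _AA_INDEX:
                raise ValueError(f"invalid residue code {aa!r} at {pos}")


@dataclass
class SubstrateTable:
    """Ordered collection of cleavage-site records with provenance."""

    records: list[SubstrateRecord]
    source: str = ""
    positions: tuple[str, ...] = NONPRIME_POSITIONS

    def __post_init__(self) -> None:
        posset = set(self.positions)
        for rec in self.records:
            if set(rec.residues) != posset:
                raise ValueError(
                    f"record {rec.substrate_id!r} has positions {sorted(rec.residues)}, "
                    f"table expects {sorted(posset)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{**{"substrate_id": r.substrate_id}, **dict(r.residues)} for r in self.records]
        )


@dataclass
class SpecificityProfile:
    """Cleavage entropy and residue counts per substrate position."""

    entropy_by_position: dict[str, float]
    counts_by_position: dict[str, np.ndarray]
    n_records: int = 0
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos, s in self.entropy_by_position.items():
            rows.append({"position": pos, "entropy": s,
                         "n_observed": int(self.counts_by_position[pos].sum())})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "source": self.source,
            "n_records": self.n_records,
            "entropy_by_position": self.entropy_by_position,
            "counts_by_position": {
                pos: {a: int(c) for a, c in zip(AMINO_ACIDS, counts) if c}
                for pos, counts in self.counts_by_position.items()
            },
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _clean_residue(value) -> str | None:
    """Normalise a table cell to a one-letter code, 'X', or None (invalid)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    s = str(value).strip().upper()
    if s in ("", "-", ".", "NA", "NAN"):
        return UNKNOWN
    if s == UNKNOWN or s in _AA_INDEX:
        return s
    return None


def read_substrate_table(
    path: str | Path,
    positions: Sequence[str] = NONPRIME_POSITIONS,
    *,
    window_column: str | None = None,
    cleavage_offset: int | None = None,
    source: str | None = None,
) -> SubstrateTable:
    """Read a MEROPS-style substrate table from a delimited text file.

    Two layouts are supported:

    * column mode (default): one column per position label (``P6`` … ``P1``);
      missing cells become ``"X"``;
    * window mode: ``window_column`` names a column holding a contiguous
      residue string, and ``cleavage_offset`` gives the 0-based index of the
      first residue *after* the cleavage site (so the P1 residue is at
      ``cleavage_offset - 1``).

    Rows containing residue codes outside the 20-letter alphabet (plus
    ``"X"``) are dropped with a logged warning.  The delimiter is sniffed.
    """
    path = Path(path)
    positions = tuple(positions)
    for pos in positions:
        if pos not in _KNOWN_POSITIONS:
            raise ValueError(f"unknown position label {pos!r}")
    if not path.exists() or not path.read_text().strip():
        raise ValueError(f"substrate table {path} is empty")
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"substrate table {path} is empty") from None
    except Exception:  # delimiter sniffing fails on single-column files
        df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"substrate table {path} contains no records")

    id_col = next((c for c in df.columns if c.lower() in ("substrate_id", "substrate", "id")), None)

    records: list[SubstrateRecord] = []
    n_dropped = 0
    for i, row in df.iterrows():
        sid = str(row[id_col]) if id_col is not None else f"row{i + 1}"
        if window_column is not None:
            if cleavage_offset is None:
                raise ValueError("window mode requires cleavage_offset")
            window = str(row[window_column]).strip().upper()
            resmap = {}
            for pos in positions:
                depth = int(pos[1:])  # Pn is n residues N-terminal of the bond
                idx = cleavage_offset - depth
                resmap[pos] = window[idx] if 0 <= idx < len(window) else UNKNOWN
        else:
            missing = [p for p in positions if p not in df.columns]
            if missing:
                raise ValueError(f"table lacks position columns {missing}")
            resmap = {pos: row[pos] for pos in positions}
        cleaned = {pos: _clean_residue(v) for pos, v in resmap.items()}
        if any(v is None for v in cleaned.values()):
            bad = {p: resmap[p] for p, v in cleaned.items() if v is None}
            logger.warning("dropping substrate %s: invalid residue code(s) %s", sid, bad)
            n_dropped += 1
            continue
        records.append(SubstrateRecord(substrate_id=sid, residues=cleaned))

    if n_dropped:
        logger.warning("dropped %d of %d rows with invalid residue codes", n_dropped, len(df))
    if not records:
        raise ValueError(f"no valid substrate records in {path}")
    return SubstrateTable(records=records, source=source or str(path.name), positions=positions)


def positional_counts(table: SubstrateTable, position: str) -> np.ndarray:
    """Residue counts (length-20 vector, alphabet order) at one position."""
    if position not in table.positions:
        raise ValueError(f"position {position!r} not in table positions {table.positions}")
    counts = np.zeros(len(AMINO_ACIDS), dtype=int)
    n_unknown = 0
    for rec in table.records:
        aa = rec.residues[position]
        if aa == UNKNOWN:
            n_unknown += 1
        else:
            counts[_AA_INDEX[aa]] += 1
    if n_unknown:
        logger.info("position %s: %d unknown residues excluded", position, n_unknown)
    return counts


def positional_frequencies(table: SubstrateTable, position: str) -> np.ndarray:
    """Relative residue frequencies at one position; ``"X"`` excluded.

    Raises :class:`UninformativePositionError` if every record is unknown.
    """
    counts = positional_counts(table, position)
    total = counts.sum()
    if total == 0:
        raise UninformativePositionError(
            f"all residues at {position} are unknown; position is uninformative"
        )
    return counts / total


def cleavage_entropy(frequencies: np.ndarray, pseudocount: float = 0.0) -> float:
    """Normalised Shannon entropy of a residue frequency vector.

    ``S = -sum_a f_a log(f_a) / log(20)`` over residues with nonzero
    frequency (``0·log 0 = 0``).  An optional additive ``pseudocount`` is
    applied to the (unnormalised) frequencies before renormalisation.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or len(f) != len(AMINO_ACIDS):
        raise ValueError("expected a length-20 frequency vector")
    if pseudocount:
        f = f + pseudocount
    total = f.sum()
    if total <= 0:
        raise ValueError("frequency vector sums to zero")
    f = f / total
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(AMINO_ACIDS)))


def cleavage_entropy_profile(
    table: SubstrateTable,
    positions: Sequence[str] | None = None,
    pseudocount: float = 0.0,
) -> SpecificityProfile:
    """Cleavage entropy at every (non-prime) position of a substrate table."""
    if len(table) == 0:
        raise ValueError("cannot compute a specificity profile from an empty table")
    if positions is None:
        positions = [p for p in table.positions if not p.endswith("'")]
    entropy: dict[str, float] = {}
    counts: dict[str, np.ndarray] = {}
    for pos in positions:
        c = positional_counts(table, pos)
        if c.sum() == 0:
            raise UninformativePositionError(
                f"all residues at {pos} are unknown; position is uninformative"
            )
        counts[pos] = c
        entropy[pos] = cleavage_entropy(c.astype(float), pseudocount=pseudocount)
    return SpecificityProfile(
        entropy_by_position=entropy,
        counts_by_position=counts,
        n_records=len(table),
        source=table.source,
    )
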