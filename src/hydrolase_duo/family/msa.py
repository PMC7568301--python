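"""Reference-anchored multiple-sequence-alignment analysis.

All per-position outputs are numbered on the ungapped reference
sequence (1-based), the convention used when speaking of, e.g.,
"position 131" of a query enzyme within its family alignment.
Conservation is scored as the relative entropy (KL divergence, bits)
of a column's residue distribution to a background distribution —
pooled family frequencies by default, optionally uniform — clipped to
[0, log₂20].  The modal residue and its frequency are reported
alongside as the plainer alternative score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ReferencedMSA",
    "identity_to_reference",
    "conservation_profile",
    "cys_pair_conservation",
    "CysConservation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
MAX_SCORE_BITS = math.log2(len(AMINO_ACIDS))


@dataclass(frozen=True)
class ReferencedMSA:
    """An alignment with one row designated as the numbering reference."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]  # aligned, gapped sequences
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must align")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if self.reference_id not in self.ids:
            raise KeyError(f"reference id {self.reference_id!r} not in alignment")
        bad = set(self.reference) - set(AMINO_ACIDS) - {GAP}
        if bad:
            raise ValueError(f"reference contains non-standard letters {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path: str | Path, reference_id: str) -> "ReferencedMSA":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(
            ids=tuple(r.id for r in records),
            rows=tuple(str(r.seq).upper() for r in records),
            reference_id=reference_id,
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.rows):
                fh.write(f">{name}\n{row}\n")

    @property
    def reference(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_columns(self) -> np.ndarray:
        """Alignment columns where the reference is ungapped, in order.

        Index i of this array is reference position i+1 (1-based).
        """
        return np.array([c for c, a in enumerate(self.reference) if a != GAP])

    def column_of_position(self, position: int) -> int:
        """Alignment column of a 1-based reference position."""
        cols = self.reference_columns
        if not (1 <= position <= len(cols)):
            raise IndexError(
                f"reference position {position} out of range 1..{len(cols)}"
            )
        return int(cols[position - 1])

    def column(self, col: int) -> str:
        return "".join(row[col] for row in self.rows)


def identity_to_reference(msa: ReferencedMSA) -> pd.DataFrame:
    """Percent identity of every row to the reference, input order kept.

    Identity = matching ungapped positions / columns where at least one
    of the pair is ungapped × 100 (gap–gap columns are excluded from
    the denominator).
    """
    ref = msa.reference
    out = []
    for name, row in zip(msa.ids, msa.rows):
        matches = denom = 0
        for a, b in zip(ref, row):
            if a == GAP and b == GAP:
                continue
            denom += 1
            if a == b:
                matches += 1
        out.append((name, 100.0 * matches / denom if denom else float("nan")))
    return pd.DataFrame(out, columns=["id", "identity_pct"])


def conservation_profile(
    msa: ReferencedMSA, background: str | np.ndarray = "pooled"
) -> pd.DataFrame:
    """Per-reference-position conservation table.

    Columns: position (1-based reference numbering), ref_residue,
    per-residue frequencies (20 columns, summing to 1 over non-gap
    letters), gap_fraction, modal_residue, modal_frequency, and
    score_bits = KL(column ‖ background) clipped to [0, log₂20].
    Positions whose column is all-gap outside the reference get a
    missing (NaN) score, never zero.
    """
    if msa.n_sequences < 2:
        raise ValueError("conservation needs at least 2 sequences")
    if isinstance(background, str):
        if background == "uniform":
            bg = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        elif background == "pooled":
            pooled = np.zeros(len(AMINO_ACIDS))
            for row in msa.rows:
                for a in row:
                    i = _AA_INDEX.get(a)
                    if i is not None:
                        pooled[i] += 1
            if pooled.sum() == 0:
                raise ValueError("alignment contains no standard residues")
            bg = pooled / pooled.sum()
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()

    ref = msa.reference
    records = []
    for pos, col_idx in enumerate(msa.reference_columns, start=1):
        col = msa.column(int(col_idx))
        counts = np.zeros(len(AMINO_ACIDS))
        gaps = 0
        for a in col:
            i = _AA_INDEX.get(a)
            if i is None:
                gaps += 1
            else:
                counts[i] += 1
        total = counts.sum()
        rec: dict = {
            "position": pos,
            "ref_residue": ref[col_idx],
            "gap_fraction": gaps / len(col),
        }
        if total == 0:
            freqs = np.full(len(AMINO_ACIDS), np.nan)
            rec.update(modal_residue="", modal_frequency=np.nan, score_bits=np.nan)
        else:
            freqs = counts / total
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(freqs > 0, freqs * np.log2(freqs / bg), 0.0)
            score = float(np.clip(terms.sum(), 0.0, MAX_SCORE_BITS))
            modal = int(np.argmax(counts))
            rec.update(
                modal_residue=AMINO_ACIDS[modal],
                modal_frequency=float(freqs[modal]),
                score_bits=score,
            )
        for a, f in zip(AMINO_ACIDS, freqs):
            rec[f"freq_{a}"] = f
        records.append(rec)
    return pd.DataFrame(records)


@dataclass(frozen=True)
class CysConservation:
    """Cysteine conservation at disulfide positions of the reference."""

    per_position: pd.DataFrame  # position, cys_fraction
    per_pair: pd.DataFrame  # pos_a, pos_b, both_cys_fraction


def cys_pair_conservation(
    msa: ReferencedMSA, pairs: list[tuple[int, int]]
) -> CysConservation:
    """Cys fraction at each reference position and joint fraction per pair.

    ``pairs`` are (pos_a, pos_b) disulfide partners in 1-based
    reference numbering.
    """
    positions = sorted({p for pair in pairs for p in pair})
    cols = {p: msa.column(msa.column_of_position(p)) for p in positions}
    n = msa.n_sequences
    per_pos = pd.DataFrame(
        {
            "position": positions,
            "cys_fraction": [sum(a == "C" for a in cols[p]) / n for p in positions],
        }
    )
    rows = []
    for a, b in pairs:
        both = sum(x == "C" and y == "C" for x, y in zip(cols[a], cols[b])) / n
        rows.append((a, b, both))
    per_pair = pd.DataFrame(rows, columns=["pos_a", "pos_b", "both_cys_fraction"])
    return CysConservation(per_position=per_pos, per_pair=per_pair)
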