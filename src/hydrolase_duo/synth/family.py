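"""Synthetic protein families with controlled conservation and subfamilies.

Each family is generated from per-column consensus residues and
conservation levels: a sequence carries the consensus at a column with
probability equal to that column's conservation, otherwise a uniform
draw from the other 19 residues.  Two subfamilies are created by
assigning subfamily B a different consensus at a chosen fraction of
columns (the divergence), which is the planted signal that subfamily
classification and tree grouping must recover.  A noise-free copy of
the subfamily-A consensus is included as the reference row, playing
the role of the query enzyme the family is profiled against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..family.msa import AMINO_ACIDS, ReferencedMSA

__all__ = ["FamilySpec", "FamilyData", "gen_family_msa"]


@dataclass(frozen=True)
class FamilySpec:
    """Specification of a synthetic family alignment."""

    n_sequences: int = 40
    length: int = 60
    conservation: float | tuple[float, ...] = 0.8
    n_subfamilies: int = 2
    divergence: float = 0.5  # fraction of columns where subfamily consensus differs
    indel_rate: float = 0.0  # per-cell deletion (gap) probability
    planted: dict[int, tuple[str, float]] = field(default_factory=dict)
    #: planted columns: 1-based position -> (residue, conservation)
    reference_id: str = "query"

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        levels = (
            [self.conservation] * self.length
            if isinstance(self.conservation, (int, float))
            else list(self.conservation)
        )
        if len(levels) != self.length:
            raise ValueError("per-column conservation must match the alignment length")
        if any(not 0.0 <= c <= 1.0 for c in levels):
            raise ValueError("conservation levels must lie in [0, 1]")
        for pos, (res, cons) in self.planted.items():
            if not 1 <= pos <= self.length:
                raise ValueError(f"planted position {pos} outside 1..{self.length}")
            if res not in AMINO_ACIDS:
                raise ValueError(f"planted residue {res!r} is not a standard amino acid")
            if not 0.0 <= cons <= 1.0:
                raise ValueError("planted conservation must lie in [0, 1]")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel rate must lie in [0, 1)")
        if self.n_subfamilies not in (1, 2):
            raise ValueError("only 1 or 2 subfamilies are supported")

    @property
    def conservation_levels(self) -> np.ndarray:
        if isinstance(self.conservation, (int, float)):
            levels = np.full(self.length, float(self.conservation))
        else:
            levels = np.asarray(self.conservation, dtype=float)
        out = levels.copy()
        for pos, (_res, cons) in self.planted.items():
            out[pos - 1] = cons
        return out


@dataclass(frozen=True)
class FamilyData:
    """A generated family: alignment, ground truth, subfamily labels."""

    msa: ReferencedMSA
    truth: pd.DataFrame  # position, consensus_a, consensus_b, conservation
    labels: dict[str, str]  # sequence id -> subfamily ("A"/"B"; reference -> "A")


def gen_family_msa(spec: FamilySpec, seed: int) -> FamilyData:
    """Generate a labeled family alignment; pure function of (spec, seed)."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    levels = spec.conservation_levels

    cons_a = rng.choice(len(aa), size=spec.length)
    for pos, (res, _c) in spec.planted.items():
        cons_a[pos - 1] = AMINO_ACIDS.index(res)
    cons_b = cons_a.copy()
    if spec.n_subfamilies == 2 and spec.divergence > 0:
        free = [c for c in range(spec.length) if (c + 1) not in spec.planted]
        n_div = int(round(spec.divergence * len(free)))
        div_cols = rng.choice(free, size=n_div, replace=False)
        for c in div_cols:
            shift = rng.integers(1, len(aa))
            cons_b[c] = (cons_a[c] + shift) % len(aa)

    n_a = spec.n_sequences - spec.n_sequences // 2 if spec.n_subfamilies == 2 else spec.n_sequences
    ids, rows, labels = [], [], {}
    for k in range(spec.n_sequences):
        sub = "A" if (spec.n_subfamilies == 1 or k < n_a) else "B"
        consensus = cons_a if sub == "A" else cons_b
        res_idx = consensus.copy()
        mutate = rng.random(spec.length) >= levels
        if mutate.any():
            # uniform over the 19 non-consensus residues
            offs = rng.integers(1, len(aa), size=int(mutate.sum()))
            res_idx[mutate] = (res_idx[mutate] + offs) % len(aa)
        row = aa[res_idx]
        if spec.indel_rate > 0:
            row = np.where(rng.random(spec.length) < spec.indel_rate, "-", row)
        name = f"{sub}_{k:04d}"
        ids.append(name)
        rows.append("".join(row))
        labels[name] = sub

    ids.append(spec.reference_id)
    rows.append("".join(aa[cons_a]))
    labels[spec.reference_id] = "A"

    truth = pd.DataFrame(
        {
            "position": np.arange(1, spec.length + 1),
            "consensus_a": list("".join(aa[cons_a])),
            "consensus_b": list("".join(aa[cons_b])),
            "conservation": levels,
        }
    )
    msa = ReferencedMSA(ids=tuple(ids), rows=tuple(rows), reference_id=spec.reference_id)
    return FamilyData(msa=msa, truth=truth, labels=labels)
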