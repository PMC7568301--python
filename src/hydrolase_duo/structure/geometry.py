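"""Geometric analyses: disulfides, catalytic triads, contacts, trajectories.

All distances are Euclidean in Å and are invariant under rigid motions
of the coordinates.  Hydrogen-bond plausibility uses a 3.5 Å
heavy-atom cutoff; disulfide detection uses a 2.3 Å Sγ–Sγ cutoff
(covalent S–S bonds sit near 2.05 Å), applied strictly (≤).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MAIN_CHAIN_ATOMS, Structure

__all__ = [
    "DisulfideBond",
    "TriadGeometry",
    "DistanceSeries",
    "find_disulfides",
    "triad_geometry",
    "residue_min_distance",
    "distance_stats",
    "DistanceStats",
    "parse_residue_id",
]

HBOND_CUTOFF = 3.5
DISULFIDE_CUTOFF = 2.3


def parse_residue_id(rid: str | tuple[str, int]) -> tuple[str, int]:
    """Accept ('A', 225) or 'A:225' residue identifiers."""
    if isinstance(rid, tuple):
        return rid[0], int(rid[1])
    chain, _, num = rid.partition(":")
    if not num:
        raise ValueError(f"residue id {rid!r} must look like 'A:225'")
    return chain, int(num)


@dataclass(frozen=True)
class DisulfideBond:
    """A Sγ–Sγ bond between two cysteines."""

    cys_a: tuple[str, int]  # (chain, author residue number)
    cys_b: tuple[str, int]
    distance: float  # Å


def find_disulfides(structure: Structure, cutoff: float = DISULFIDE_CUTOFF) -> list[DisulfideBond]:
    """All disulfide bonds: CYS Sγ pairs with distance ≤ cutoff.

    Each cysteine joins at most one bond; conflicts are resolved
    greedily by ascending distance.  Cysteines lacking an Sγ atom are
    skipped with a warning.
    """
    cys = structure.atoms[
        (structure.atoms["resname"] == "CYS") & (~structure.atoms["is_hydrogen"])
    ]
    sg_rows = []
    for (chain, resseq), group in cys.groupby(["chain", "resseq"], sort=True):
        sg = group[group["name"] == "SG"]
        if sg.empty:
            warnings.warn(f"cysteine {chain}:{resseq} has no SG atom; skipped", stacklevel=2)
            continue
        sg_rows.append(((str(chain), int(resseq)), sg.iloc[0][["x", "y", "z"]].to_numpy(float)))
    candidates = []
    for i in range(len(sg_rows)):
        for j in range(i + 1, len(sg_rows)):
            d = float(np.linalg.norm(sg_rows[i][1] - sg_rows[j][1]))
            if d <= cutoff:
                candidates.append((d, sg_rows[i][0], sg_rows[j][0]))
    candidates.sort()
    used: set[tuple[str, int]] = set()
    bonds = []
    for d, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        bonds.append(DisulfideBond(cys_a=a, cys_b=b, distance=d))
    bonds.sort(key=lambda bond: (bond.cys_a[0], bond.cys_a[1]))
    return bonds


@dataclass(frozen=True)
class TriadGeometry:
    """Catalytic-triad distances with hydrogen-bond plausibility flags."""

    ser_og_his_ne2: float  # Å
    his_nd1_asp_od: float  # Å, nearer of Oδ1/Oδ2
    ser_og_substrate: float | None  # Å, optional carbonyl-carbon distance
    ser_his_bonded: bool
    his_asp_bonded: bool
    substrate_in_range: bool | None


def _atom_coord(res: pd.DataFrame, names: list[str], what: str) -> np.ndarray:
    for name in names:
        hit = res[res["name"] == name]
        if not hit.empty:
            return hit.iloc[0][["x", "y", "z"]].to_numpy(float)
    raise KeyError(f"{what}: none of atoms {names} present")


def triad_geometry(
    structure: Structure,
    ser: str | tuple[str, int],
    his: str | tuple[str, int],
    asp: str | tuple[str, int],
    substrate_atom: tuple[str | tuple[str, int], str] | None = None,
    hbond_cutoff: float = HBOND_CUTOFF,
) -> TriadGeometry:
    """Defining distances of a Ser–His–Asp catalytic triad.

    Measures Ser Oγ–His Nε2 and His Nδ1–Asp Oδ (nearer of Oδ1/Oδ2),
    optionally the Ser Oγ to a named substrate atom, and flags each
    against the hydrogen-bond cutoff.  Residue types are checked.
    """
    expectations = [(ser, "SER"), (his, "HIS"), (asp, "ASP")]
    residues = []
    for rid, expected in expectations:
        chain, num = parse_residue_id(rid)
        res = structure.residue(chain, num)
        found = res.iloc[0]["resname"]
        if found != expected:
            raise TypeError(f"residue {chain}:{num} is {found}, expected {expected}")
        residues.append(res)
    ser_res, his_res, asp_res = residues
    og = _atom_coord(ser_res, ["OG"], "catalytic serine")
    ne2 = _atom_coord(his_res, ["NE2"], "catalytic histidine")
    nd1 = _atom_coord(his_res, ["ND1"], "catalytic histidine")
    d_ser_his = float(np.linalg.norm(og - ne2))
    od_dists = []
    for od_name in ("OD1", "OD2"):
        hit = asp_res[asp_res["name"] == od_name]
        if not hit.empty:
            od_dists.append(float(np.linalg.norm(nd1 - hit.iloc[0][["x", "y", "z"]].to_numpy(float))))
    if not od_dists:
        raise KeyError("aspartate has neither OD1 nor OD2")
    d_his_asp = min(od_dists)
    d_sub = None
    if substrate_atom is not None:
        rid, atom_name = substrate_atom
        chain, num = parse_residue_id(rid)
        sub_res = structure.residue(chain, num)
        pos = _atom_coord(sub_res, [atom_name], "substrate")
        d_sub = float(np.linalg.norm(og - pos))
    return TriadGeometry(
        ser_og_his_ne2=round(d_ser_his, 2),
        his_nd1_asp_od=round(d_his_asp, 2),
        ser_og_substrate=None if d_sub is None else round(d_sub, 2),
        ser_his_bonded=d_ser_his <= hbond_cutoff,
        his_asp_bonded=d_his_asp <= hbond_cutoff,
        substrate_in_range=None if d_sub is None else d_sub <= hbond_cutoff,
    )


def residue_min_distance(
    structure: Structure,
    res_a: str | tuple[str, int],
    res_b: str | tuple[str, int],
    atom_subset: str = "all-heavy",
) -> tuple[float, tuple[str, str]]:
    """Minimum pairwise distance between two residues (2-decimal Å).

    ``atom_subset`` ∈ {'all-heavy', 'main-chain', 'side-chain'}.
    Returns the distance and the achieving (atom_a, atom_b) pair.
    """
    if atom_subset not in ("all-heavy", "main-chain", "side-chain"):
        raise ValueError(f"unknown atom subset {atom_subset!r}")
    ca, na = parse_residue_id(res_a)
    cb, nb = parse_residue_id(res_b)
    if (ca, na) == (cb, nb):
        raise ValueError(f"self-distance for residue {ca}:{na} is undefined")

    def _select(res: pd.DataFrame) -> pd.DataFrame:
        res = res[~res["is_hydrogen"]]
        if atom_subset == "main-chain":
            res = res[res["name"].isin(MAIN_CHAIN_ATOMS)]
        elif atom_subset == "side-chain":
            res = res[~res["name"].isin(MAIN_CHAIN_ATOMS)]
        return res

    ra = _select(structure.residue(ca, na))
    rb = _select(structure.residue(cb, nb))
    if ra.empty or rb.empty:
        raise ValueError(f"empty {atom_subset} selection for one of the residues")
    xa = ra[["x", "y", "z"]].to_numpy(float)
    xb = rb[["x", "y", "z"]].to_numpy(float)
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return round(float(d[i, j]), 2), (str(ra.iloc[i]["name"]), str(rb.iloc[j]["name"]))


@dataclass(frozen=True)
class DistanceSeries:
    """A distance time series over trajectory frames."""

    time_ns: np.ndarray
    distance: np.ndarray  # Å

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ns, dtype=float)
        d = np.asarray(self.distance, dtype=float)
        if t.shape != d.shape:
            raise ValueError("time and distance arrays must align")
        object.__setattr__(self, "time_ns", t)
        object.__setattr__(self, "distance", d)

    @property
    def mean(self) -> float:
        return float(np.mean(self.distance))

    @property
    def sd(self) -> float:
        return float(np.std(self.distance, ddof=1))


@dataclass(frozen=True)
class DistanceStats:
    """Summary of a distance series: mean ± sd and contact occupancy."""

    mean: float
    sd: float
    occupancy: float  # fraction of frames at or below the threshold
    threshold: float
    n_frames: int

    def __str__(self) -> str:
        return f"{self.mean:.1f} ± {self.sd:.1f} Å (occupancy {self.occupancy:.0%} ≤ {self.threshold} Å)"


def distance_stats(
    series: DistanceSeries | np.ndarray, threshold: float = HBOND_CUTOFF
) -> DistanceStats:
    """Mean, standard deviation and occupancy of a distance series."""
    d = series.distance if isinstance(series, DistanceSeries) else np.asarray(series, float)
    if len(d) < 2:
        raise ValueError("need at least 2 frames; sd is undefined for a single frame")
    return DistanceStats(
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=1)),
        occupancy=float(np.mean(d <= threshold)),
        threshold=threshold,
        n_frames=len(d),
    )


def trajectory_distances(
    models: list[Structure],
    atom_a: tuple[str | tuple[str, int], str],
    atom_b: tuple[str | tuple[str, int], str],
    frame_spacing_ns: float = 1.0,
) -> DistanceSeries:
    """Distance between two tagged atoms across multi-model frames."""
    dists = []
    for st in models:
        (rid_a, name_a), (rid_b, name_b) = atom_a, atom_b
        pa = _atom_coord(st.residue(*parse_residue_id(rid_a)), [name_a], "atom A")
        pb = _atom_coord(st.residue(*parse_residue_id(rid_b)), [name_b], "atom B")
        dists.append(float(np.linalg.norm(pa - pb)))
    t = np.arange(len(dists)) * frame_spacing_ns
    return DistanceSeries(time_ns=t, distance=np.array(dists))
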