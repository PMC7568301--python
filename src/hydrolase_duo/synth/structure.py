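"""Toy protein structures with planted geometric features.

The builder lays out minimal residues (backbone N/CA/C/O plus the
side-chain atoms the geometry operations look at) in well-separated
clusters along x, so the only sub-cutoff contacts are the planted
ones: Sγ–Sγ disulfide pairs at stated distances, a Ser/His/Asp triad
with stated hydrogen-bond geometry, and a main-chain contact pair
mimicking a lid-closure linkage.  A companion generator draws a
normally distributed atom-pair distance series, standing in for an MD
hydrogen-bond trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..structure.core import Structure
from ..structure.geometry import DistanceSeries

__all__ = ["ToyStructureSpec", "gen_toy_structure", "gen_distance_trajectory",
           "gen_distance_models"]

#: Spacing between residue clusters, Å; far beyond any detection cutoff.
_CLUSTER_SPACING = 25.0


@dataclass(frozen=True)
class ToyStructureSpec:
    """Planted features of a synthetic structure."""

    disulfide_distances: tuple[float, ...] = (2.05, 2.05, 2.05, 2.05, 2.05)
    triad: bool = True
    ser_og_his_ne2: float = 2.8  # Å
    his_nd1_asp_od: float = 2.7  # Å
    linkage: bool = True
    linkage_distance: float = 2.90  # Å, nearest main-chain pair
    chain: str = "A"

    def __post_init__(self) -> None:
        if not (self.disulfide_distances or self.triad or self.linkage):
            raise ValueError("feature list is empty: plant at least one feature")
        if any(d <= 0 for d in self.disulfide_distances):
            raise ValueError("disulfide distances must be positive")


def _backbone(cx: float, y_off: float = 5.0) -> list[tuple[str, str, float, float, float]]:
    """Minimal main-chain atoms, offset in y so they never undercut planted contacts."""
    return [
        ("N", "N", cx - 0.5, y_off, 0.0),
        ("CA", "C", cx, y_off + 1.0, 0.0),
        ("C", "C", cx + 0.5, y_off, 0.0),
        ("O", "O", cx + 0.5, y_off - 1.2, 0.0),
    ]


def gen_toy_structure(spec: ToyStructureSpec = ToyStructureSpec()) -> Structure:
    """Build the planted structure; geometry is exact by construction."""
    records: list[tuple] = []
    serial = 0
    resseq = 0

    def add_atom(name: str, element: str, resname: str, rs: int, x: float, y: float, z: float):
        nonlocal serial
        serial += 1
        records.append((serial, name, element, "", 1.0, resname, rs, spec.chain, x, y, z))

    def add_residue(resname: str, cx: float, side: list[tuple[str, str, float, float, float]]):
        nonlocal resseq
        resseq += 1
        for name, el, x, y, z in _backbone(cx):
            add_atom(name, el, resname, resseq, x, y, z)
        for name, el, x, y, z in side:
            add_atom(name, el, resname, resseq, x, y, z)
        return resseq

    cluster = 0.0
    pairs = []
    for d in spec.disulfide_distances:
        a = add_residue("CYS", cluster, [("CB", "C", cluster, 1.5, 0.0),
                                         ("SG", "S", cluster, 0.0, 0.0)])
        b = add_residue("CYS", cluster + d, [("CB", "C", cluster + d, 1.5, 0.0),
                                             ("SG", "S", cluster + d, 0.0, 0.0)])
        pairs.append((a, b))
        cluster += _CLUSTER_SPACING

    triad_ids = None
    if spec.triad:
        og_x = cluster
        ne2_x = og_x + spec.ser_og_his_ne2
        nd1_x = ne2_x + 2.2  # across the imidazole ring
        od_x = nd1_x + spec.his_nd1_asp_od
        ser = add_residue("SER", og_x, [("CB", "C", og_x - 1.0, 1.0, 0.0),
                                        ("OG", "O", og_x, 0.0, 0.0)])
        his = add_residue("HIS", ne2_x, [("CG", "C", ne2_x + 1.0, 1.5, 0.0),
                                         ("NE2", "N", ne2_x, 0.0, 0.0),
                                         ("ND1", "N", nd1_x, 0.0, 0.0)])
        asp = add_residue("ASP", od_x, [("CG", "C", od_x + 1.0, 1.5, 0.0),
                                        ("OD1", "O", od_x, 0.0, 0.0),
                                        ("OD2", "O", od_x + 1.0, 0.5, 0.0)])
        triad_ids = (ser, his, asp)
        cluster += _CLUSTER_SPACING

    linkage_ids = None
    if spec.linkage:
        # TYR O (at y = 3.8) and ALA N, straight below it, are the nearest
        # main-chain pair, separated by exactly the stated distance
        ty = cluster
        tyr = add_residue("TYR", ty, [("CB", "C", ty, 1.5, 3.0),
                                      ("OH", "O", ty, 2.5, 6.0)])
        resseq += 1
        ala = resseq
        base = 3.8 - spec.linkage_distance  # y of the ALA amide nitrogen
        add_atom("N", "N", "ALA", ala, ty + 0.5, base, 0.0)
        add_atom("CA", "C", "ALA", ala, ty + 0.5, base - 1.5, 0.0)
        add_atom("C", "C", "ALA", ala, ty + 1.5, base - 2.0, 0.0)
        add_atom("O", "O", "ALA", ala, ty + 2.5, base - 2.0, 0.0)
        add_atom("CB", "C", "ALA", ala, ty - 0.5, base - 2.5, 0.0)
        linkage_ids = (tyr, ala)

    atoms = pd.DataFrame(
        records,
        columns=["serial", "name", "element", "altloc", "occupancy",
                 "resname", "resseq", "chain", "x", "y", "z"],
    )
    st = Structure(atoms=atoms, name="toy")
    st.planted_disulfides = pairs  # type: ignore[attr-defined]
    st.planted_triad = triad_ids  # type: ignore[attr-defined]
    st.planted_linkage = linkage_ids  # type: ignore[attr-defined]
    return st


def gen_distance_trajectory(
    mean: float = 2.0,
    sd: float = 0.2,
    n_frames: int = 10_000,
    seed: int = 0,
    frame_spacing_ns: float = 0.015,
) -> DistanceSeries:
    """Normally distributed atom-pair distance series, N(mean, sd²) Å."""
    if sd < 0 or mean <= 0 or n_frames < 2:
        raise ValueError("need mean > 0, sd >= 0 and at least 2 frames")
    rng = np.random.default_rng(seed)
    d = mean + sd * rng.standard_normal(n_frames)
    t = np.arange(n_frames) * frame_spacing_ns
    return DistanceSeries(time_ns=t, distance=d)


def gen_distance_models(
    mean: float = 2.0,
    sd: float = 0.2,
    n_frames: int = 100,
    seed: int = 0,
    chain: str = "A",
) -> list[Structure]:
    """Multi-model frames of a two-atom system with N(mean, sd²) separation.

    Frame i holds a SER Oγ at the origin and a HIS Nε2 at the sampled
    distance along x, mirroring a hydrogen-bond trace stored as a
    multi-model PDB.
    """
    series = gen_distance_trajectory(mean, sd, n_frames, seed)
    models = []
    for i, d in enumerate(series.distance, start=1):
        atoms = pd.DataFrame(
            [
                (1, "OG", "O", "", 1.0, "SER", 1, chain, 0.0, 0.0, 0.0),
                (2, "NE2", "N", "", 1.0, "HIS", 2, chain, float(d), 0.0, 0.0),
            ],
            columns=["serial", "name", "element", "altloc", "occupancy",
                     "resname", "resseq", "chain", "x", "y", "z"],
        )
        models.append(Structure(atoms=atoms, model_id=i, name="trace"))
    return models
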