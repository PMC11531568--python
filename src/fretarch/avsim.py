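"""Grid-based accessible-volume (AV) simulation of dye positions.

A dye on a flexible linker is modelled geometrically: the linker is a
cylinder (length, width) anchored at an attachment atom, the dye an
ellipsoid approximated by up to three radii (the 3AV model).  A cubic
grid is flooded outward from the attachment atom; a grid point belongs to
the accessible volume of dye radius ``R_i`` when

* the shortest linker path from the attachment to the point — a geodesic
  through 26-neighbour grid steps that clears every protein atom's van
  der Waals surface by half the linker width — is no longer than the
  linker length, and
* a sphere of radius ``R_i`` centred at the point does not overlap any
  protein atom (vdW radii).

The 3AV cloud is the union of the three single-radius AVs with equal 1/3
weights (uniform within each sub-AV); no contact-surface reweighting is
applied.  Inter-dye statistics are taken over the product measure of two
weighted clouds; efficiencies use the static, isotropic (kappa^2 = 2/3)
averaging regime:  mean_E = <1/(1+(r/R0)^6)> and the FRET-averaged
distance R_E = R0*(1/mean_E - 1)^(1/6).

The attachment anchor defaults to the CB atom of the labelled residue,
whose side-chain atoms beyond CB are ignored as obstacles (the dye
replaces the side chain).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .photophysics import efficiency_to_distance
from .presets import vdw_radius_table
from .units import angstrom_to_nm

__all__ = [
    "AVParameters",
    "AccessibleVolume",
    "StructureModel",
    "EmptyAVError",
    "load_structure",
    "structure_from_atom_array",
    "compute_av",
    "pair_distance_stats",
    "predict_pair_table",
    "DimerFormPrediction",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA"}


class EmptyAVError(RuntimeError):
    """The labelling site is fully buried: no sterically allowed dye position."""


@dataclass(frozen=True)
class AVParameters:
    """Linker/dye geometry for one AV simulation (all lengths in Å)."""

    linker_length: float
    linker_width: float
    dye_radii: tuple[float, ...]
    grid_spacing: float = 1.0
    attachment_atom: str = "CB"

    def __post_init__(self) -> None:
        if self.linker_length <= 0:
            raise ValueError("linker_length must be positive")
        if any(r <= 0 for r in self.dye_radii) or not self.dye_radii:
            raise ValueError("dye radii must be positive and non-empty")
        if not (0 < self.grid_spacing <= self.linker_length / 5.0):
            raise ValueError("grid_spacing must lie in (0, linker_length/5]")
        object.__setattr__(self, "dye_radii", tuple(float(r) for r in self.dye_radii))


@dataclass
class AccessibleVolume:
    """Weighted cloud of sterically allowed dye positions (Å)."""

    points: np.ndarray  # (n, 3)
    weights: np.ndarray  # (n,), sum to 1
    attachment: np.ndarray  # (3,)
    params: AVParameters

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.points) != len(self.weights):
            raise ValueError("points/weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("negative AV weights")
        total = self.weights.sum()
        if total <= 0:
            raise EmptyAVError("accessible volume is empty")
        self.weights = self.weights / total

    @property
    def centroid(self) -> np.ndarray:
        return self.weights @ self.points

    def __len__(self) -> int:
        return len(self.points)

    def to_xyz(self) -> str:
        """XYZ point-cloud export (pseudo-atoms named AV)."""
        lines = [str(len(self)), "accessible volume point cloud"]
        lines += [f"AV {x:.3f} {y:.3f} {z:.3f}" for x, y, z in self.points]
        return "\n".join(lines) + "\n"

    def to_dx(self) -> str:
        """OpenDX scalar-grid export of the AV weight density."""
        spacing = self.params.grid_spacing
        lo = self.points.min(axis=0)
        idx = np.rint((self.points - lo) / spacing).astype(int)
        shape = idx.max(axis=0) + 1
        grid = np.zeros(shape)
        np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), self.weights)
        nx, ny, nz = shape
        head = [
            f"object 1 class gridpositions counts {nx} {ny} {nz}",
            f"origin {lo[0]:.3f} {lo[1]:.3f} {lo[2]:.3f}",
            f"delta {spacing:.3f} 0 0",
            f"delta 0 {spacing:.3f} 0",
            f"delta 0 0 {spacing:.3f}",
            f"object 2 class gridconnections counts {nx} {ny} {nz}",
            f"object 3 class array type double rank 0 items {grid.size} data follows",
        ]
        flat = grid.ravel()
        body = [
            " ".join(f"{v:.6e}" for v in flat[i : i + 3])
            for i in range(0, len(flat), 3)
        ]
        return "\n".join(head + body) + "\n"


@dataclass
class StructureModel:
    """A parsed structure: coordinates plus per-atom vdW radii.

    Thin wrapper over a biotite ``AtomArray`` adding radius lookup and
    chain/residue addressing used by the AV and metric modules.
    """

    array: "object"  # biotite.structure.AtomArray
    vdw: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        table = vdw_radius_table()
        self.vdw = np.array(
            [table.get(str(e).upper(), table["default"]) for e in self.array.element]
        )
        if not np.all(np.isfinite(self.array.coord)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def coords(self) -> np.ndarray:
        return self.array.coord

    def select(self, chain: str | None = None, res_ids: Sequence[int] | None = None,
               atom_names: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask over atoms."""
        mask = np.ones(len(self.array), dtype=bool)
        if chain is not None:
            mask &= self.array.chain_id == chain
        if res_ids is not None:
            mask &= np.isin(self.array.res_id, np.asarray(res_ids))
        if atom_names is not None:
            mask &= np.isin(self.array.atom_name, np.asarray(atom_names))
        return mask

    def atom_coord(self, chain: str, res_id: int, atom_name: str) -> np.ndarray:
        mask = self.select(chain=chain, res_ids=[res_id], atom_names=[atom_name])
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"atom {atom_name} of {chain}:{res_id} not found")
        return self.array.coord[idx[0]].copy()


def load_structure(pdb_text: str) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Malformed ATOM/HETATM records are reported with their line numbers
    before parsing is delegated to biotite.
    """
    bad = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                [float(line[c0:c1]) for c0, c1 in ((30, 38), (38, 46), (46, 54))]
            except (ValueError, IndexError):
                bad.append(lineno)
    if bad:
        raise ValueError(f"malformed coordinate records at lines {bad}")
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(_io.StringIO(pdb_text))
    array = pdb.get_structure(model=1)
    return StructureModel(array=array)


def structure_from_atom_array(array) -> StructureModel:
    return StructureModel(array=array)


def _sphere_offsets(radius_vox: float) -> np.ndarray:
    """Integer voxel offsets within a Euclidean radius (in voxel units)."""
    r = int(np.ceil(radius_vox))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius_vox**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _blocked_mask(
    shape: tuple[int, int, int],
    origin: np.ndarray,
    spacing: float,
    atom_coords: np.ndarray,
    atom_vdw: np.ndarray,
    clearance: float,
) -> np.ndarray:
    """True where a grid point is within (vdw + clearance) of any atom."""
    blocked = np.zeros(shape, dtype=bool)
    if len(atom_coords) == 0:
        return blocked
    # group atoms by vdW radius so sphere stencils are built once per radius
    for vdw in np.unique(atom_vdw):
        offsets = _sphere_offsets((vdw + clearance) / spacing)
        for a in atom_coords[atom_vdw == vdw]:
            center = np.rint((a - origin) / spacing).astype(int)
            vox = offsets + center
            # exact Euclidean check in world units (center rounding shifts)
            pos = origin + vox * spacing
            ok = np.linalg.norm(pos - a, axis=1) < vdw + clearance
            vox = vox[ok]
            inside = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
            vox = vox[inside]
            blocked[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return blocked


_NEIGHBOR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def _geodesic_distances(
    free: np.ndarray, spacing: float, source_idx: tuple[int, int, int]
) -> np.ndarray:
    """Shortest 26-neighbour path lengths (Å) from the source voxel through
    free voxels; +inf where unreachable or blocked."""
    shape = free.shape
    flat_ids = -np.ones(shape, dtype=np.int64)
    free_vox = np.argwhere(free)
    flat_ids[free_vox[:, 0], free_vox[:, 1], free_vox[:, 2]] = np.arange(len(free_vox))
    rows, cols, data = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        nb = free_vox + off
        inside = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        src = np.flatnonzero(inside)
        nb = nb[inside]
        nb_id = flat_ids[nb[:, 0], nb[:, 1], nb[:, 2]]
        ok = nb_id >= 0
        rows.append(src[ok])
        cols.append(nb_id[ok])
        data.append(
            np.full(ok.sum(), spacing * float(np.linalg.norm(off)))
        )
    n = len(free_vox)
    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    src_id = flat_ids[source_idx]
    if src_id < 0:
        raise EmptyAVError("attachment point is sterically blocked")
    dist_flat = dijkstra(graph, indices=src_id, directed=False)
    out = np.full(shape, np.inf)
    out[free_vox[:, 0], free_vox[:, 1], free_vox[:, 2]] = dist_flat
    return out


def compute_av(
    structure: StructureModel,
    chain: str,
    res_id: int,
    params: AVParameters,
) -> AccessibleVolume:
    """Accessible volume of a dye attached at ``chain:res_id``.

    Flood fill (Dijkstra on the 26-neighbour grid graph) from the
    attachment atom; see the module docstring for the admission rules.
    """
    attachment = structure.atom_coord(chain, res_id, params.attachment_atom)

    # obstacles: everything except the labelled residue's side chain
    # (beyond CB) and the attachment atom itself — the dye replaces them
    site_mask = structure.select(chain=chain, res_ids=[res_id])
    sidechain = site_mask & ~np.isin(structure.array.atom_name, list(_BACKBONE))
    obstacle = ~sidechain
    coords = structure.coords[obstacle]
    vdw = structure.vdw[obstacle]

    # restrict to atoms that can influence the AV box
    max_r = max(params.dye_radii)
    reach = params.linker_length + max_r + vdw.max(initial=0.0) + params.grid_spacing
    near = np.linalg.norm(coords - attachment, axis=1) <= reach
    coords, vdw = coords[near], vdw[near]

    spacing = params.grid_spacing
    half = int(np.ceil(params.linker_length / spacing))
    n_side = 2 * half + 1
    origin = attachment - half * spacing
    shape = (n_side, n_side, n_side)

    path_blocked = _blocked_mask(
        shape, origin, spacing, coords, vdw, params.linker_width / 2.0
    )
    free = ~path_blocked
    center = (half, half, half)
    if not free[center]:
        # the anchor voxel may fall inside a neighbouring atom's clearance
        # zone; start from the nearest free voxel within two steps instead
        # search outward far enough to clear one vdW + linker-half-width
        # shell in the worst case
        max_search = int(np.ceil((vdw.max(initial=1.8) + params.linker_width / 2.0) / spacing)) + 1
        found = None
        for radius in range(1, max_search + 1):
            offs = _sphere_offsets(radius)
            cand = offs + np.array(center)
            cand = cand[np.all((cand >= 0) & (cand < n_side), axis=1)]
            cand = [tuple(c) for c in cand if free[tuple(c)]]
            if cand:
                found = min(
                    cand,
                    key=lambda c: np.linalg.norm((np.array(c) - half) * spacing),
                )
                break
        if found is None:
            raise EmptyAVError(
                f"attachment at {chain}:{res_id} is fully buried"
            )
        center = found

    geo = _geodesic_distances(free, spacing, center)
    # when the anchor voxel itself was blocked, the linker first has to
    # reach the source voxel; count that stretch against its length
    source_pos = origin + np.array(center) * spacing
    geo += float(np.linalg.norm(source_pos - attachment))
    within = geo <= params.linker_length

    ax = origin[0] + spacing * np.arange(n_side)
    ay = origin[1] + spacing * np.arange(n_side)
    az = origin[2] + spacing * np.arange(n_side)
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")

    all_points: list[np.ndarray] = []
    all_weights: list[np.ndarray] = []
    n_sub = 0
    for r_dye in params.dye_radii:
        clash = _blocked_mask(shape, origin, spacing, coords, vdw, r_dye)
        allowed = within & ~clash
        n_pts = int(allowed.sum())
        if n_pts == 0:
            continue
        pts = np.stack([gx[allowed], gy[allowed], gz[allowed]], axis=1)
        all_points.append(pts)
        all_weights.append(np.full(n_pts, 1.0 / n_pts))
        n_sub += 1
    if n_sub == 0:
        raise EmptyAVError(f"no allowed dye position at {chain}:{res_id}")
    if n_sub < len(params.dye_radii):
        warnings.warn(
            f"{len(params.dye_radii) - n_sub} of {len(params.dye_radii)} "
            "sub-volumes empty; weights renormalized over the rest",
            stacklevel=2,
        )
    points = np.concatenate(all_points)
    weights = np.concatenate([w / n_sub for w in all_weights])
    return AccessibleVolume(
        points=points, weights=weights, attachment=attachment, params=params
    )


def pair_distance_stats(
    av_donor: AccessibleVolume,
    av_acceptor: AccessibleVolume,
    R0_nm: float,
    max_exhaustive_pairs: int = 4_000_000,
    n_sample_pairs: int = 400_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Inter-dye statistics over the product of two weighted AV clouds.

    Returns ``(mean_R, mean_E, R_E)`` with distances in nm.  All point
    pairs are enumerated when the product size permits; otherwise pairs
    are subsampled by drawing indices from each cloud's weight
    distribution with a fixed seed.
    """
    n1, n2 = len(av_donor), len(av_acceptor)
    if n1 == 0 or n2 == 0:
        raise EmptyAVError("empty accessible volume in pair statistics")
    if n1 * n2 <= max_exhaustive_pairs:
        mean_r_A = 0.0
        mean_e = 0.0
        chunk = max(1, max_exhaustive_pairs // max(n2, 1))
        for lo in range(0, n1, chunk):
            block = av_donor.points[lo : lo + chunk]
            w1 = av_donor.weights[lo : lo + chunk]
            d = np.linalg.norm(
                block[:, None, :] - av_acceptor.points[None, :, :], axis=2
            )
            w = w1[:, None] * av_acceptor.weights[None, :]
            mean_r_A += float(np.sum(w * d))
            e = 1.0 / (1.0 + (angstrom_to_nm(d) / R0_nm) ** 6)
            mean_e += float(np.sum(w * e))
    else:
        rng = np.random.default_rng(seed)
        i = rng.choice(n1, size=n_sample_pairs, p=av_donor.weights)
        j = rng.choice(n2, size=n_sample_pairs, p=av_acceptor.weights)
        d = np.linalg.norm(av_donor.points[i] - av_acceptor.points[j], axis=1)
        mean_r_A = float(np.mean(d))
        mean_e = float(np.mean(1.0 / (1.0 + (angstrom_to_nm(d) / R0_nm) ** 6)))
    mean_r = angstrom_to_nm(mean_r_A)
    r_e = efficiency_to_distance(mean_e, R0_nm)
    return mean_r, mean_e, r_e


@dataclass
class DimerFormPrediction:
    """Predicted inter-dye distances/efficiencies for one candidate dimer."""

    form: str
    entries: dict  # pair label -> {"mean_R": nm, "mean_E": ..., "R_E": nm}
    provenance: dict = field(default_factory=dict)

    def distances(self, key: str = "R_E") -> dict:
        return {pair: vals[key] for pair, vals in self.entries.items()}


def predict_pair_table(
    structure: StructureModel,
    sites: dict,
    donor_params: AVParameters,
    acceptor_params: AVParameters,
    r0_nm: dict,
    form: str = "",
) -> DimerFormPrediction:
    """Predicted {T-T, T-H/H-T, H-H} distance/efficiency table for a dimer.

    ``sites`` maps a site label (e.g. ``"T"``, ``"H"``) to a pair of
    ``(chain, res_id)`` tuples, one per protomer.  For each combination
    X-Y the donor AV is computed at site X of protomer 1 and the acceptor
    AV at site Y of protomer 2; the mixed combinations T-H and H-T are
    averaged into the single ``T-H/H-T`` entry.  ``r0_nm`` maps pair
    labels to Förster radii in nm.
    """
    labels = sorted(sites)
    av_cache: dict = {}

    def get_av(label: str, protomer: int, params: AVParameters) -> AccessibleVolume:
        key = (label, protomer, id(params))
        if key not in av_cache:
            chain, res = sites[label][protomer]
            av_cache[key] = compute_av(structure, chain, res, params)
        return av_cache[key]

    raw: dict = {}
    for x in labels:
        for y in labels:
            av_d = get_av(x, 0, donor_params)
            av_a = get_av(y, 1, acceptor_params)
            pair = f"{x}-{y}"
            r0 = r0_nm.get(pair) or r0_nm.get(f"{y}-{x}") or r0_nm.get(
                f"{x}-{y}/{y}-{x}"
            ) or r0_nm.get(f"{y}-{x}/{x}-{y}")
            if r0 is None:
                raise KeyError(f"no Förster radius supplied for pair {pair}")
            mean_r, mean_e, r_e = pair_distance_stats(av_d, av_a, r0)
            raw[pair] = {"mean_R": mean_r, "mean_E": mean_e, "R_E": r_e, "R0": r0}

    entries: dict = {}
    for x in labels:
        entries[f"{x}-{x}"] = {
            k: raw[f"{x}-{x}"][k] for k in ("mean_R", "mean_E", "R_E")
        }
    for i, x in enumerate(labels):
        for y in labels[i + 1 :]:
            a, b = raw[f"{x}-{y}"], raw[f"{y}-{x}"]
            mean_e = 0.5 * (a["mean_E"] + b["mean_E"])
            entries[f"{x}-{y}/{y}-{x}"] = {
                "mean_R": 0.5 * (a["mean_R"] + b["mean_R"]),
                "mean_E": mean_e,
                "R_E": efficiency_to_distance(mean_e, a["R0"]),
            }
    return DimerFormPrediction(
        form=form,
        entries=entries,
        provenance={
            "sites": {k: list(map(list, v)) for k, v in sites.items()},
            "donor_params": vars(donor_params) | {"dye_radii": list(donor_params.dye_radii)},
            "acceptor_params": vars(acceptor_params)
            | {"dye_radii": list(acceptor_params.dye_radii)},
        },
    )
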