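"""Structural descriptors: domain angle, radius of gyration, RMSD, SASA
and buried interface area.

The inter-domain angle θ quantifies the relative orientation of the Sema
and IPT1 domains of the MET ectodomain: two vectors are built, each
connecting the centres of mass of two residue ranges, and θ is the angle
between them.  The default ranges (182–200 / 464–479 for the Sema-side
vector and 561–657 / 655–657 for the IPT1-side vector) follow the
published definition; the second pair overlaps as printed, which is
flagged with a warning but honoured, and all ranges are configurable.

The radius of gyration over Cα atoms (unit masses by default) classifies
ectodomain conformations as extended (Rg > 45 Å) or collapsed.  SASA uses
Shrake–Rupley sphere quadrature (960 points/atom by default, probe
1.4 Å); the buried interface between two chain groups is reported per
side, (SASA(A) + SASA(B) − SASA(A∪B)) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .avsim import StructureModel
from .presets import vdw_radius_table

__all__ = [
    "ThetaDefinition",
    "ConformationCall",
    "theta_angle",
    "radius_of_gyration",
    "classify_conformation",
    "rmsd",
    "sasa",
    "interface_area",
]

RG_THRESHOLD_DEFAULT = 45.0  # Å, extended/collapsed boundary


@dataclass(frozen=True)
class ThetaDefinition:
    """Residue ranges defining the two domain-orientation vectors.

    Each vector runs from the centre of mass of its first residue range
    to that of its second range (inclusive bounds, structure numbering).
    """

    v1_start: tuple[int, int] = (182, 200)
    v1_end: tuple[int, int] = (464, 479)
    v2_start: tuple[int, int] = (561, 657)
    v2_end: tuple[int, int] = (655, 657)
    chain: str | None = None

    def __post_init__(self) -> None:
        for r in (self.v1_start, self.v1_end, self.v2_start, self.v2_end):
            if r[0] > r[1]:
                raise ValueError(f"empty residue range {r}")
        for a, b in ((self.v1_start, self.v1_end), (self.v2_start, self.v2_end)):
            if a[1] >= b[0] and b[1] >= a[0]:
                warnings.warn(
                    f"residue ranges {a} and {b} overlap; using as given",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class ConformationCall:
    Rg: float
    label: str  # "extended" | "collapsed"
    threshold: float

    def __post_init__(self) -> None:
        expected = "extended" if self.Rg > self.threshold else "collapsed"
        if self.label != expected:
            raise ValueError("label inconsistent with threshold comparison")


def _range_com(
    structure: StructureModel,
    res_range: tuple[int, int],
    chain: str | None,
    masses: np.ndarray | None,
) -> np.ndarray:
    mask = structure.select(
        chain=chain, res_ids=list(range(res_range[0], res_range[1] + 1))
    )
    if not mask.any():
        raise ValueError(f"residue range {res_range} resolves to no atoms")
    coords = structure.coords[mask]
    m = masses[mask] if masses is not None else np.ones(mask.sum())
    return (m[:, None] * coords).sum(axis=0) / m.sum()


def theta_angle(
    structure: StructureModel,
    definition: ThetaDefinition | None = None,
    mass_weighted: bool = True,
) -> float:
    """Angle (degrees, in [0, 180]) between the two domain vectors.

    Centres of mass use standard atomic masses when available and
    ``mass_weighted`` is set; otherwise unit masses.
    """
    if definition is None:
        definition = ThetaDefinition()
    masses = None
    if mass_weighted:
        try:
            import biotite.structure.info as info

            masses = np.array(
                [info.mass(str(e)) or 1.0 for e in structure.array.element]
            )
        except Exception:
            masses = None
    d = definition
    v1 = _range_com(structure, d.v1_end, d.chain, masses) - _range_com(
        structure, d.v1_start, d.chain, masses
    )
    v2 = _range_com(structure, d.v2_end, d.chain, masses) - _range_com(
        structure, d.v2_start, d.chain, masses
    )
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length domain vector")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Rg (Å) = sqrt(sum m_i |r_i − r_com|² / sum m_i); unit masses default."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) == 0:
        raise ValueError("need at least one atom")
    m = np.ones(len(coords)) if masses is None else np.asarray(masses, float)
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((coords - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_calpha(structure: StructureModel, chain: str | None = None) -> float:
    """Radius of gyration over Cα atoms with unit masses."""
    mask = structure.select(chain=chain, atom_names=["CA"])
    if not mask.any():
        raise ValueError("no CA atoms in selection")
    return radius_of_gyration(structure.coords[mask])


def classify_conformation(
    Rg: float, threshold: float = RG_THRESHOLD_DEFAULT
) -> ConformationCall:
    """Extended iff Rg strictly exceeds the threshold (45 Å default)."""
    if Rg < 0:
        raise ValueError("Rg must be non-negative")
    return ConformationCall(
        Rg=Rg,
        label="extended" if Rg > threshold else "collapsed",
        threshold=threshold,
    )


def rmsd(frame: np.ndarray, reference: np.ndarray) -> float:
    """RMSD (Å) after optimal least-squares superposition (Kabsch)."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("selections have mismatched atom counts")
    import biotite.structure as struc

    fitted, _ = struc.superimpose(reference, frame)
    return float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))


def sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    point_number: int = 960,
    mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area.

    Returns ``(total_A2, per_atom_A2)`` over the atoms in ``mask`` (all
    atoms by default), with only those atoms present as occluders — pass
    a pre-sliced structure to control the occluding environment.
    """
    import biotite.structure as struc

    array = structure.array if mask is None else structure.array[mask]
    vdw = structure.vdw if mask is None else structure.vdw[mask]
    per_atom = struc.sasa(
        array,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii=vdw,
    )
    per_atom = np.nan_to_num(per_atom)
    return float(per_atom.sum()), per_atom


def interface_area(
    structure: StructureModel,
    group_a_chains: list[str],
    group_b_chains: list[str],
    probe_radius: float = 1.4,
    point_number: int = 960,
) -> float:
    """Buried surface per side between two chain groups (Å²):
    ``(SASA(A) + SASA(B) − SASA(A∪B)) / 2``."""
    set_a, set_b = set(group_a_chains), set(group_b_chains)
    if not set_a or not set_b:
        raise ValueError("both chain groups must be nonempty")
    if set_a & set_b:
        raise ValueError(f"chain groups overlap: {sorted(set_a & set_b)}")
    chains = set(str(c) for c in structure.array.chain_id)
    missing = (set_a | set_b) - chains
    if missing:
        raise ValueError(f"chains not in structure: {sorted(missing)}")

    def group_sasa(chain_set: set[str]) -> float:
        mask = np.isin(structure.array.chain_id, sorted(chain_set))
        sub = StructureModel(array=structure.array[mask])
        total, _ = sasa(sub, probe_radius, point_number)
        return total

    a = group_sasa(set_a)
    b = group_sasa(set_b)
    ab = group_sasa(set_a | set_b)
    return (a + b - ab) / 2.0
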