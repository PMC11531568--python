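"""Synthetic inputs for every pipeline stage.

Three generators:

* ALEX camera traces with known ground truth — a donor/acceptor pair at a
  set distance, with leakage, direct excitation, detection imbalance,
  excitation imbalance, exponential single-step photobleaching, Poisson
  background and shot noise (optionally Gaussian read noise);
* single-molecule-localization fields with known cluster density,
  localization precision and blinking structure, emulating dSTORM output;
* toy PDB structures for exercising the structural modules without
  external downloads.

Camera physics is deliberately simplified: Poisson shot noise plus
optional Gaussian read noise.  The EMCCD excess-noise factor is omitted,
so simulated intensity variances slightly underestimate those of real
EM-amplified data.  Photobleaching is single-step per fluorophore with a
geometric (discrete-exponential) waiting time; FRET traces contain no
blinking — blinking is modelled only in the localization-field generator,
where it matters for linking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .photophysics import distance_to_efficiency
from .presets import fluorophore_pair
from .traces import AlexTrace, CorrectionFactors

__all__ = [
    "TraceSimParams",
    "GroundTruth",
    "FieldParams",
    "TraceSet",
    "simulate_alex_trace",
    "simulate_trace_cohort",
    "simulate_localization_field",
    "make_toy_structure",
]


@dataclass(frozen=True)
class TraceSimParams:
    """Settings for one simulated ALEX trace.

    ``true_distance`` (nm) sets the true efficiency through the Förster
    relation of the named fluorophore pair.  ``mean_donor_photons`` is the
    mean absorbed-donor photon budget per donor-excitation frame; bleach
    rates are per-frame probabilities; ``background_per_channel`` is a
    mean photon count added to every channel and frame.
    """

    true_distance: float = 4.8
    fluorophore_pair_id: str = "cy3b_T"
    frames: int = 800
    exposure_ms: float = 100.0
    mean_donor_photons: float = 300.0
    alpha: float = 0.05
    delta: float = 0.05
    gamma: float = 1.0
    beta: float = 1.0
    donor_bleach_rate: float = 0.002
    acceptor_bleach_rate: float = 0.004
    background_per_channel: float = 10.0
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("donor_bleach_rate", "acceptor_bleach_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "true_distance",
            "mean_donor_photons",
            "background_per_channel",
            "alpha",
            "delta",
            "gamma",
            "beta",
            "read_noise_sd",
            "exposure_ms",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v} must be finite and non-negative")
        if self.true_distance <= 0:
            raise ValueError("true_distance must be positive")
        if self.frames < 1:
            raise ValueError("need at least one frame")

    @property
    def factors(self) -> CorrectionFactors:
        return CorrectionFactors(
            alpha=self.alpha, delta=self.delta, gamma=self.gamma, beta=self.beta
        )


@dataclass(frozen=True)
class GroundTruth:
    """Truth sidecar for a simulated trace."""

    true_efficiency: float
    bleach_frames: dict  # {"donor": int|None, "acceptor": int|None}
    factors: CorrectionFactors
    species: str = "fret"  # fret | donor_only | acceptor_only

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_efficiency <= 1.0):
            raise ValueError("true efficiency outside [0, 1]")


@dataclass(frozen=True)
class FieldParams:
    """Settings for a simulated localization field.

    The field is a square of area ``area_um2``; cluster centres follow a
    homogeneous Poisson process with intensity ``cluster_density``
    (clusters/µm²).  Each cluster emits a number of blinking events drawn
    from a Poisson with mean ``events_per_cluster``; an event spans a
    geometric run of consecutive frames (mean ``mean_event_frames``), one
    localization per frame, each Gaussian-scattered around the cluster
    centre with ``localization_precision`` (nm) per axis.  Uniform noise
    localizations are added with ``noise_density`` (localizations/µm²).
    """

    area_um2: float = 100.0
    cluster_density: float = 2.8
    events_per_cluster: float = 25.0
    mean_event_frames: float = 3.0
    localization_precision: float = 10.0
    frame_count: int = 10_000
    noise_density: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("area must be positive")
        for name in ("cluster_density", "noise_density", "events_per_cluster"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.localization_precision < 0:
            raise ValueError("localization precision must be >= 0")


@dataclass
class TraceSet:
    """A labelled cohort of simulated traces with per-trace truth."""

    traces: list[AlexTrace]
    truths: list[GroundTruth]

    def by_species(self, species: str) -> list[AlexTrace]:
        return [t for t, g in zip(self.traces, self.truths) if g.species == species]

    def __len__(self) -> int:
        return len(self.traces)


def _bleach_frame(rng: np.random.Generator, rate: float) -> int | None:
    """First dark frame index; geometric waiting time, None if never."""
    if rate <= 0.0:
        return None
    return int(rng.geometric(rate))


def simulate_alex_trace(
    params: TraceSimParams,
    species: str = "fret",
    rng: np.random.Generator | None = None,
) -> tuple[AlexTrace, GroundTruth]:
    """Simulate one ALEX trace (one row per excitation-alternation cycle).

    Expected pre-bleach channel means (``N_D`` = mean donor photon budget,
    ``E`` = true efficiency, ``bg`` = background):

        I_DD = (1 - E) * N_D + bg
        I_DA = gamma*E*N_D + alpha*(1-E)*N_D + delta*I_AA_expected + bg
        I_AA = beta * gamma * N_D + bg

    After the acceptor bleaches the FRET and direct-excitation terms drop
    to zero and the donor intensity rises to ``N_D + bg``; after the donor
    bleaches only background (plus any direct-excitation term while the
    acceptor lives) remains in the donor-excitation channels.  Identical
    parameters and seed reproduce the identical trace.
    """
    if species not in ("fret", "donor_only", "acceptor_only"):
        raise ValueError(f"unknown species {species!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    E = (
        distance_to_efficiency(
            params.true_distance, fluorophore_pair(params.fluorophore_pair_id).R0
        )
        if species == "fret"
        else 0.0
    )
    has_donor = species != "acceptor_only"
    has_acceptor = species != "donor_only"

    db = _bleach_frame(rng, params.donor_bleach_rate) if has_donor else None
    ab = _bleach_frame(rng, params.acceptor_bleach_rate) if has_acceptor else None

    t = np.arange(params.frames)
    donor_on = has_donor & (t < (db if db is not None else params.frames + 1))
    acc_on = has_acceptor & (t < (ab if ab is not None else params.frames + 1))

    N_D = params.mean_donor_photons * donor_on
    e_eff = np.where(acc_on, E, 0.0)
    aa_exp = params.beta * params.gamma * params.mean_donor_photons * acc_on
    dd_exp = (1.0 - e_eff) * N_D
    da_exp = (
        params.gamma * e_eff * N_D
        + params.alpha * (1.0 - e_eff) * N_D
        + params.delta * aa_exp
    )

    bg = params.background_per_channel
    I_DD = rng.poisson(dd_exp + bg).astype(float)
    I_DA = rng.poisson(da_exp + bg).astype(float)
    I_AA = rng.poisson(aa_exp + bg).astype(float)
    if params.read_noise_sd > 0:
        I_DD += rng.normal(0.0, params.read_noise_sd, params.frames)
        I_DA += rng.normal(0.0, params.read_noise_sd, params.frames)
        I_AA += rng.normal(0.0, params.read_noise_sd, params.frames)

    trace = AlexTrace(frame=t, I_DD=I_DD, I_DA=I_DA, I_AA=I_AA)
    truth = GroundTruth(
        true_efficiency=E,
        bleach_frames={"donor": db, "acceptor": ab},
        factors=params.factors,
        species=species,
    )
    return trace, truth


def simulate_trace_cohort(
    n_traces: int,
    params: TraceSimParams,
    donor_only_fraction: float = 0.0,
    acceptor_only_fraction: float = 0.0,
) -> TraceSet:
    """A labelled mixture of FRET, donor-only and acceptor-only traces.

    Species counts are the rounded fractions of ``n_traces``; per-trace
    random streams are spawned deterministically from ``params.seed``.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    for f in (donor_only_fraction, acceptor_only_fraction):
        if not (0.0 <= f <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
    if donor_only_fraction + acceptor_only_fraction > 1.0:
        raise ValueError("species fractions sum above 1")

    n_donor = int(round(donor_only_fraction * n_traces))
    n_acceptor = int(round(acceptor_only_fraction * n_traces))
    n_fret = n_traces - n_donor - n_acceptor
    species = ["fret"] * n_fret + ["donor_only"] * n_donor + ["acceptor_only"] * n_acceptor

    seeds = np.random.SeedSequence(params.seed).spawn(n_traces)
    traces, truths = [], []
    for i, (sp, ss) in enumerate(zip(species, seeds)):
        tr, gt = simulate_alex_trace(params, sp, rng=np.random.default_rng(ss))
        tr.trace_id = f"trace_{i:05d}"
        traces.append(tr)
        truths.append(gt)
    return TraceSet(traces=traces, truths=truths)


def simulate_localization_field(
    params: FieldParams,
) -> tuple["pd.DataFrame", np.ndarray]:
    """Simulate a dSTORM-like localization table.

    Returns a DataFrame with columns ``x_nm, y_nm, frame`` and the true
    cluster-centre coordinates (nm) as an (n, 2) array.
    """
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    side_nm = np.sqrt(params.area_um2) * 1000.0

    n_clusters = rng.poisson(params.cluster_density * params.area_um2)
    centers = rng.uniform(0.0, side_nm, size=(n_clusters, 2))

    xs, ys, frames = [], [], []
    for cx, cy in centers:
        n_events = max(1, rng.poisson(params.events_per_cluster))
        for _ in range(n_events):
            start = rng.integers(0, max(1, params.frame_count))
            length = rng.geometric(1.0 / max(1.0, params.mean_event_frames))
            for k in range(length):
                f = start + k
                if f >= params.frame_count:
                    break
                xs.append(cx + rng.normal(0.0, params.localization_precision))
                ys.append(cy + rng.normal(0.0, params.localization_precision))
                frames.append(f)

    n_noise = rng.poisson(params.noise_density * params.area_um2)
    if n_noise:
        xs.extend(rng.uniform(0.0, side_nm, n_noise))
        ys.extend(rng.uniform(0.0, side_nm, n_noise))
        frames.extend(rng.integers(0, max(1, params.frame_count), n_noise))

    table = pd.DataFrame({"x_nm": xs, "y_nm": ys, "frame": frames})
    table = table.sort_values("frame", kind="stable").reset_index(drop=True)
    return table, centers


def make_toy_structure(atoms: Sequence[dict]):
    """Build a toy structure from explicit atom records.

    Each record is a dict with keys ``name`` (atom name), ``element``,
    ``chain``, ``res_id``, ``res_name`` and ``coord`` (3 floats, Å).
    Returns ``(AtomArray, pdb_text)``; the PDB text round-trips through
    the reader at PDB coordinate precision (0.001 Å).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    seen = set()
    array = struc.AtomArray(len(atoms))
    for i, rec in enumerate(atoms):
        coord = np.asarray(rec["coord"], dtype=float)
        if not np.all(np.isfinite(coord)):
            raise ValueError(f"non-finite coordinates in atom record {i}")
        key = (rec["chain"], rec["res_id"], rec["name"])
        if key in seen:
            raise ValueError(f"duplicate atom identifier {key}")
        seen.add(key)
        array.coord[i] = coord
        array.atom_name[i] = rec["name"]
        array.element[i] = rec["element"]
        array.chain_id[i] = rec["chain"]
        array.res_id[i] = rec["res_id"]
        array.res_name[i] = rec.get("res_name", "UNK")
        array.hetero[i] = False
    pdb = PDBFile()
    pdb.set_structure(array)
    text = "\n".join(pdb.lines) + "\n"
    return array, text
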