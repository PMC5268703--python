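"""Synthetic trajectory ensembles with known ground truth.

The generator emulates the statistical structure of an MD study of a
helical domain — several replicas of a few hundred frames, α-helical Cα
traces at controlled mutual angles with an optional kink, and charged
side-chain pseudo-atoms whose minimum O–N distance follows a two-state
(closed/open) Markov chain with state-conditional Gaussian distances —
without any force-field realism.  Every stage of the analysis pipeline
can therefore be validated by parameter recovery.

All randomness flows from the single config seed through
``numpy.random.SeedSequence`` spawning: the root sequence spawns one
child per replica, and each replica child spawns one stream for
coordinate noise plus one per salt-bridge model.  No global state is
touched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .helixgeom import fit_helix_axis
from .io_core import (
    AnalysisConfig,
    Atom,
    HelixDefinition,
    ResiduePair,
    StructureFrame,
    Topology,
    TrajectoryEnsemble,
    read_trajectory,
    write_structure,
)

#: Canonical α-helix parameters: rise per residue (Å), twist per residue
#: (degrees) and Cα radius (Å).
CANONICAL_RISE = 1.5
CANONICAL_TWIST = 100.0
CANONICAL_RADIUS = 2.3

#: Minimum physical O–N distance; Gaussian draws at or below this are redrawn.
MIN_DISTANCE = 0.5


@dataclass
class TwoStateSaltBridgeModel:
    """Two-state Markov model of a salt-bridge O–N distance.

    Per-frame stay probabilities define the chain; the distance in each
    frame is drawn from the Gaussian of the current state (closed: bridge
    formed, open: broken), truncated at ``MIN_DISTANCE``.
    """

    p_stay_closed: float = 0.7
    p_stay_open: float = 0.55
    closed_distance: tuple[float, float] = (2.8, 0.2)
    open_distance: tuple[float, float] = (6.0, 1.0)

    def __post_init__(self):
        for p in (self.p_stay_closed, self.p_stay_open):
            if not 0.0 < p < 1.0:
                raise ConfigurationError("stay probabilities must be in (0, 1)")
        if self.closed_distance[0] >= self.open_distance[0]:
            raise ConfigurationError("closed mean distance must be < open mean")

    @property
    def stationary_closed(self) -> float:
        """Stationary probability of the closed (contact) state."""
        return (1.0 - self.p_stay_open) / (
            2.0 - self.p_stay_closed - self.p_stay_open
        )

    @property
    def lag1_autocorrelation(self) -> float:
        """Lag-1 autocorrelation of the state indicator."""
        return self.p_stay_closed + self.p_stay_open - 1.0


@dataclass
class SyntheticHelixSpec:
    """Placement of one ideal helix in the synthetic system."""

    name: str
    n_residues: int
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kink_angle: float = 0.0  # degrees
    kink_position: int | None = None  # residue index, strictly interior

    def __post_init__(self):
        if self.n_residues < 5:
            raise ConfigurationError("synthetic helices need >= 5 residues")


def default_helices() -> list[SyntheticHelixSpec]:
    """Two-helix system mirroring the H9/H10 pair of an LBD:

    a 21-residue helix with a 17.2° kink at its midpoint and a straight
    17-residue partner placed at 47.6° (the wild-type ensemble means of
    the study system this generator emulates).
    """
    return [
        SyntheticHelixSpec("H9", 21, kink_angle=17.2, kink_position=10),
        SyntheticHelixSpec("H10", 17, origin=(12.0, 0.0, 0.0)),
    ]


@dataclass
class SyntheticEnsembleConfig:
    """Full parameterization of the synthetic generator.

    Defaults mirror the emulated study design: four replicas per
    condition, a two-helix system at 47.6° with a 17.2° kink, and one
    salt bridge with stationary closed probability 0.6.  500 frames at
    0.2 ns spacing keep the ensemble desk-scale; synthetic frames start
    equilibrated, so no discard is needed (pair the dataset with
    ``equilibration_ns=0``).
    """

    helices: list[SyntheticHelixSpec] = field(default_factory=default_helices)
    #: target angle (degrees) between the fitted axes of helix 0 and each
    #: subsequent helix; realized exactly in the noiseless base geometry
    pair_angles: list[float] = field(default_factory=lambda: [47.6])
    saltbridge_models: list[TwoStateSaltBridgeModel] = field(
        default_factory=lambda: [TwoStateSaltBridgeModel()]
    )
    n_frames: int = 500
    frame_dt: float = 0.2  # ns
    n_replicas: int = 4
    noise_sd: float = 0.1  # Å, isotropic, helix atoms only
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ConfigurationError("frame and replica counts must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if len(self.pair_angles) != len(self.helices) - 1:
            raise ConfigurationError(
                "need one pair_angle per helix beyond the first"
            )
        for a in self.pair_angles:
            if not 0.0 <= a <= 180.0:
                raise ConfigurationError("pair angles must be in [0, 180] degrees")


def build_ideal_helix(
    n_res: int,
    rise: float = CANONICAL_RISE,
    twist: float = CANONICAL_TWIST,
    radius: float = CANONICAL_RADIUS,
    kink_angle: float = 0.0,
    kink_position: int | None = None,
) -> np.ndarray:
    """Cα trace of a canonical α-helix along +z, optionally kinked.

    The kink rigidly rotates the C-terminal segment (residues at or past
    ``kink_position``) by ``kink_angle`` degrees about an axis
    perpendicular to the helix axis through the axis point at the kink,
    so both segments remain ideal helices.
    """
    if n_res < 5:
        raise ConfigurationError(f"need at least 5 residues, got {n_res}")
    k = np.arange(n_res)
    theta = np.radians(twist) * k
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * k]
    )
    if kink_angle != 0.0:
        if kink_position is None or not 0 < kink_position < n_res - 1:
            raise ConfigurationError(
                "kink_position must lie strictly inside the helix"
            )
        pivot = np.array([0.0, 0.0, rise * kink_position])
        rot = _axis_angle_matrix(np.array([1.0, 0.0, 0.0]), np.radians(kink_angle))
        tail = coords[kink_position:]
        coords[kink_position:] = (tail - pivot) @ rot.T + pivot
    return coords


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _axis_angle_matrix(perp, np.pi)
    return _axis_angle_matrix(v / np.linalg.norm(v), np.arccos(np.clip(c, -1, 1)))


def simulate_saltbridge_series(
    model: TwoStateSaltBridgeModel,
    n_frames: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (state sequence, O–N distance series) for one salt bridge.

    States: 1 = closed, 0 = open.  The chain starts from its stationary
    distribution; distances are state-conditional Gaussians truncated at
    ``MIN_DISTANCE`` (offending draws are redrawn).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    states = np.empty(n_frames, dtype=int)
    states[0] = 1 if rng.random() < model.stationary_closed else 0
    stay = {1: model.p_stay_closed, 0: model.p_stay_open}
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        s = states[t - 1]
        states[t] = s if u[t - 1] < stay[s] else 1 - s
    means = np.where(states == 1, model.closed_distance[0], model.open_distance[0])
    sds = np.where(states == 1, model.closed_distance[1], model.open_distance[1])
    distances = rng.normal(means, sds)
    bad = distances <= MIN_DISTANCE
    while bad.any():
        distances[bad] = rng.normal(means[bad], sds[bad])
        bad = distances <= MIN_DISTANCE
    return states, distances


def _base_system(config: SyntheticEnsembleConfig):
    """Noiseless topology + base coordinates + bookkeeping.

    Helix 0 is built from its spec; every further helix is oriented so
    that the angle between its fitted axis and helix 0's fitted axis
    equals the configured pair angle exactly in the noiseless geometry.
    """
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    helix_defs: list[HelixDefinition] = []
    helix_atom_slices: list[slice] = []

    ref_axis = None
    for h_i, spec in enumerate(config.helices):
        local = build_ideal_helix(
            spec.n_residues,
            kink_angle=spec.kink_angle,
            kink_position=spec.kink_position,
        )
        if h_i == 0:
            rot = _rotation_between(np.array([0.0, 0.0, 1.0]), np.array(spec.direction))
            placed = local @ rot.T + np.array(spec.origin)
            ref_axis = fit_helix_axis(placed).axis
        else:
            # target direction: ref_axis tilted by the configured pair angle
            perp = np.cross(ref_axis, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(ref_axis, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            target = _axis_angle_matrix(
                perp, np.radians(config.pair_angles[h_i - 1])
            ) @ ref_axis
            own_axis = fit_helix_axis(local).axis
            rot = _rotation_between(own_axis, target)
            placed = local @ rot.T + np.array(spec.origin)
        chain_id = chr(ord("A") + h_i)
        start = len(atoms)
        for r in range(spec.n_residues):
            atoms.append(Atom("CA", "C", "ALA", r + 1, chain_id))
            coords.append(placed[r])
        helix_atom_slices.append(slice(start, len(atoms)))
        helix_defs.append(HelixDefinition(spec.name, chain_id, 1, spec.n_residues))

    # pseudo salt-bridge residues on chain S, placed clear of the helices
    pairs: list[ResiduePair] = []
    bridge_layout: list[dict] = []
    for m_i, _model in enumerate(config.saltbridge_models):
        anchor = np.array([45.0 + 12.0 * m_i, 0.0, 0.0])
        asp_num = 2 * m_i + 1
        arg_num = 2 * m_i + 2
        o_start = len(atoms)
        atoms.append(Atom("OD1", "O", "ASP", asp_num, "S"))
        coords.append(anchor)
        atoms.append(Atom("OD2", "O", "ASP", asp_num, "S"))
        coords.append(anchor + np.array([-2.2, 0.0, 0.0]))
        n_start = len(atoms)
        atoms.append(Atom("NE", "N", "ARG", arg_num, "S"))
        coords.append(anchor + np.array([0.0, 3.0, 0.0]))
        atoms.append(Atom("NH1", "N", "ARG", arg_num, "S"))
        coords.append(anchor + np.array([0.0, 4.35, 0.0]))
        atoms.append(Atom("NH2", "N", "ARG", arg_num, "S"))
        coords.append(anchor + np.array([0.8, 4.2, 0.0]))
        pairs.append(ResiduePair("S", asp_num, "S", arg_num, f"R{arg_num}-D{asp_num}"))
        bridge_layout.append({"anchor": anchor, "o_start": o_start, "n_start": n_start})

    topology = Topology(atoms)
    base = np.array(coords)
    return topology, base, helix_defs, helix_atom_slices, pairs, bridge_layout


def _bridge_frame_coords(anchor: np.ndarray, distance: float) -> np.ndarray:
    """N-atom positions realizing a given minimum O–N distance.

    NE sits ``distance`` from OD1 along +y; NH1/NH2 are farther, and OD2
    is offset perpendicular to the O–N line, so the minimum over all O–N
    pairs equals ``distance`` exactly.
    """
    return np.array(
        [
            anchor + np.array([0.0, distance, 0.0]),
            anchor + np.array([0.0, distance + 1.35, 0.0]),
            anchor + np.array([0.8, distance + 1.2, 0.0]),
        ]
    )


def generate_ensemble(
    config: SyntheticEnsembleConfig, out_dir: str | Path
) -> dict:
    """Write a synthetic dataset to ``out_dir`` and return its manifest.

    Files: ``topology.pdb`` (noiseless base structure), one multi-model
    ``replica_XX.pdb`` per replica, ``analysis.yaml`` (helices, pairs and
    analysis defaults for the dataset) and ``manifest.json`` recording
    every ground-truth parameter and the seed-spawning scheme.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (
        topology,
        base,
        helix_defs,
        helix_slices,
        pairs,
        bridge_layout,
    ) = _base_system(config)

    write_structure(StructureFrame(topology, base), out_dir / "topology.pdb")

    root = np.random.SeedSequence(config.seed)
    replica_seeds = root.spawn(config.n_replicas)
    traj_files = []
    truth_series = []
    for r, rep_ss in enumerate(replica_seeds):
        streams = rep_ss.spawn(1 + len(config.saltbridge_models))
        noise_rng = np.random.default_rng(streams[0])
        frames = np.repeat(base[None, :, :], config.n_frames, axis=0)
        if config.noise_sd > 0:
            for sl in helix_slices:
                frames[:, sl, :] += noise_rng.normal(
                    0.0, config.noise_sd, size=frames[:, sl, :].shape
                )
        rep_truth = {"replica": r}
        for m_i, model in enumerate(config.saltbridge_models):
            states, dists = simulate_saltbridge_series(
                model, config.n_frames, np.random.default_rng(streams[1 + m_i])
            )
            lay = bridge_layout[m_i]
            for t in range(config.n_frames):
                frames[t, lay["n_start"] : lay["n_start"] + 3, :] = (
                    _bridge_frame_coords(lay["anchor"], dists[t])
                )
            rep_truth[f"bridge_{m_i}_closed_fraction"] = float(np.mean(states))
        truth_series.append(rep_truth)
        fname = out_dir / f"replica_{r:02d}.pdb"
        write_structure(None, fname, topology=topology, coordinate_frames=list(frames))
        traj_files.append(fname.name)

    analysis = {
        "equilibration_ns": 0.0,
        "helices": [
            {
                "name": h.name,
                "chain_id": h.chain_id,
                "first_residue": h.first_residue,
                "last_residue": h.last_residue,
            }
            for h in helix_defs
        ],
        "pairs": [
            {
                "acidic": [p.acidic_chain, p.acidic_residue],
                "basic": [p.basic_chain, p.basic_residue],
                "label": p.label,
            }
            for p in pairs
        ],
        "helix_pairs": [
            [helix_defs[0].name, h.name] for h in helix_defs[1:]
        ],
    }
    with open(out_dir / "analysis.yaml", "w") as fh:
        yaml.safe_dump(analysis, fh, sort_keys=False)

    manifest = {
        "seed": config.seed,
        "seed_scheme": (
            "SeedSequence(seed).spawn(n_replicas); each replica spawns "
            "[coordinate-noise stream, one stream per salt-bridge model]"
        ),
        "n_replicas": config.n_replicas,
        "n_frames": config.n_frames,
        "frame_dt_ns": config.frame_dt,
        "noise_sd": config.noise_sd,
        "topology": "topology.pdb",
        "trajectories": traj_files,
        "helices": [asdict(h) for h in config.helices],
        "pair_angles": list(config.pair_angles),
        "saltbridges": [
            {
                **asdict(m),
                "stationary_closed": m.stationary_closed,
                "lag1_autocorrelation": m.lag1_autocorrelation,
                "pair_label": pairs[i].label,
            }
            for i, m in enumerate(config.saltbridge_models)
        ],
        "kinks": [
            {"helix": h.name, "kink_angle": h.kink_angle}
            for h in config.helices
            if h.kink_angle
        ],
        "per_replica_truth": truth_series,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_generated_ensemble(out_dir: str | Path) -> tuple[TrajectoryEnsemble, dict]:
    """Read back a generated dataset via the standard io_core readers."""
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    ensemble = read_trajectory(
        out_dir / manifest["topology"],
        [out_dir / t for t in manifest["trajectories"]],
        frame_dt=manifest["frame_dt_ns"],
    )
    return ensemble, manifest


def analysis_config_for(manifest: dict, **overrides) -> AnalysisConfig:
    """Analysis configuration matched to a generated dataset (no discard)."""
    defaults = dict(equilibration_ns=0.0, rng_seed=manifest["seed"])
    defaults.update(overrides)
    return AnalysisConfig(**defaults)
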