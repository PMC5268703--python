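"""Structure/trajectory input, selections and analysis configuration.

Single crystal structures are read with :mod:`gemmi` (which resolves
altlocs and exposes HELIX records); multi-frame trajectories (multi-model
PDB, DCD, XTC) are read with :mod:`MDAnalysis`.  All coordinates are in
ångström and all times in nanoseconds throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    EmptyAnalysisError,
    EmptyInputError,
    FormatError,
    TopologyError,
    UnsupportedResidueError,
)

# Charged side-chain heavy atoms taking part in salt bridges.
CHARGED_SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
ACIDIC_RESIDUES = ("ASP", "GLU")
BASIC_RESIDUES = ("ARG", "LYS")


@dataclass(frozen=True)
class Atom:
    """One atom of the topology (PDB v3 naming, author numbering)."""

    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    altloc: str = ""
    occupancy: float = 1.0


@dataclass
class Residue:
    chain_id: str
    residue_number: int
    residue_name: str
    #: atom name -> index into Topology.atoms / coordinate rows
    atom_index: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


class Topology:
    """Atom list plus a residue index keyed by (chain_id, residue_number)."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        self.residues: dict[tuple[str, int], Residue] = {}
        for i, atom in enumerate(self.atoms):
            key = (atom.chain_id, atom.residue_number)
            res = self.residues.get(key)
            if res is None:
                res = Residue(atom.chain_id, atom.residue_number, atom.residue_name)
                self.residues[key] = res
            if atom.name in res.atom_index:
                raise FormatError(
                    f"duplicate atom {atom.name} in residue {key} after altloc resolution"
                )
            res.atom_index[atom.name] = i

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue(self, chain_id: str, residue_number: int) -> Residue:
        try:
            return self.residues[(chain_id, residue_number)]
        except KeyError:
            raise ConfigurationError(
                f"residue {chain_id}{residue_number} not found in topology"
            ) from None

    def ca_index(self, chain_id: str, residue_number: int) -> int | None:
        res = self.residues.get((chain_id, residue_number))
        if res is None:
            return None
        return res.atom_index.get("CA")


@dataclass
class Replica:
    """Ordered frames of one trajectory: times (ns) and coordinates (Å)."""

    times: np.ndarray  # (n_frames,)
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FormatError("replica coordinates must have shape (frames, atoms, 3)")
        if len(self.times) != len(self.coordinates):
            raise FormatError("frame times and coordinates disagree in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class TrajectoryEnsemble:
    """One topology shared by one or more trajectory replicas."""

    topology: Topology
    replicas: list[Replica]

    def __post_init__(self):
        for rep in self.replicas:
            if rep.coordinates.shape[1] != self.topology.n_atoms:
                raise TopologyError(
                    f"replica has {rep.coordinates.shape[1]} atoms, "
                    f"topology has {self.topology.n_atoms}"
                )

    @property
    def n_frames(self) -> int:
        return sum(rep.n_frames for rep in self.replicas)

    def iter_frames(self) -> Iterable[tuple[int, float, np.ndarray]]:
        """Yield (replica_index, time_ns, coords) over all replicas in order."""
        for r, rep in enumerate(self.replicas):
            for t, xyz in zip(rep.times, rep.coordinates):
                yield r, float(t), xyz


@dataclass(frozen=True)
class HelixDefinition:
    """Residue span of one helix, author numbering, inclusive bounds."""

    name: str
    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self):
        if self.last_residue < self.first_residue:
            raise ConfigurationError(f"helix {self.name}: empty residue range")

    @property
    def n_residues(self) -> int:
        return self.last_residue - self.first_residue + 1


@dataclass(frozen=True)
class ResiduePair:
    """An acidic/basic residue pair whose salt bridge is monitored."""

    acidic_chain: str
    acidic_residue: int
    basic_chain: str
    basic_residue: int
    label: str = ""

    def __post_init__(self):
        if (self.acidic_chain, self.acidic_residue) == (
            self.basic_chain,
            self.basic_residue,
        ):
            raise ConfigurationError("acidic and basic residues must be distinct")

    @property
    def acidic_key(self) -> tuple[str, int]:
        return (self.acidic_chain, self.acidic_residue)

    @property
    def basic_key(self) -> tuple[str, int]:
        return (self.basic_chain, self.basic_residue)

    def display(self) -> str:
        return self.label or (
            f"{self.basic_chain}{self.basic_residue}-"
            f"{self.acidic_chain}{self.acidic_residue}"
        )


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    equilibration_ns
        Initial trajectory segment discarded before any statistic (ns).
    contact_cutoff
        Maximum O–N distance counted as an electrostatic contact (Å),
        boundary inclusive.
    hist_fraction_threshold
        Threshold for the "fraction of distances below X Å" summary (Å).
    bendix_window
        Residue window for local helix-axis points when measuring bending.
    bootstrap_reps
        Bootstrap replicates for standard errors of ensemble means.
    stride
        Frame stride for analysis (1 = every saved frame).
    hist_bin_width
        Bin width of exported distance histograms (Å).
    """

    equilibration_ns: float = 30.0
    contact_cutoff: float = 3.5
    hist_fraction_threshold: float = 4.0
    bendix_window: int = 4
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    stride: int = 1
    hist_bin_width: float = 0.2

    def __post_init__(self):
        if self.contact_cutoff <= 0 or self.hist_fraction_threshold <= 0:
            raise ConfigurationError("distance cutoffs must be positive")
        if self.equilibration_ns < 0:
            raise ConfigurationError("equilibration_ns must be >= 0")
        if self.bendix_window < 2:
            raise ConfigurationError("bendix_window must be >= 2")
        if self.bootstrap_reps < 1:
            raise ConfigurationError("bootstrap_reps must be >= 1")
        if self.stride < 1:
            raise ConfigurationError("stride must be >= 1")
        if self.hist_bin_width <= 0:
            raise ConfigurationError("hist_bin_width must be positive")


@dataclass
class StructureFrame:
    """A topology with a single coordinate frame (e.g. a crystal structure)."""

    topology: Topology
    coordinates: np.ndarray  # (n_atoms, 3)
    helices: list[HelixDefinition] = field(default_factory=list)


def _resolve_altlocs(records):
    """Keep one conformer per (chain, resid, atom name).

    Policy: highest occupancy wins; ties broken by altloc identifier order.
    ``records`` is a list of (Atom, xyz) tuples.
    """
    chosen: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for atom, xyz in records:
        key = (atom.chain_id, atom.residue_number, atom.name)
        prev = chosen.get(key)
        if prev is None:
            chosen[key] = (atom, xyz)
            order.append(key)
        else:
            pa = prev[0]
            if (atom.occupancy, _altloc_rank(atom.altloc)) > (
                pa.occupancy,
                _altloc_rank(pa.altloc),
            ):
                chosen[key] = (atom, xyz)
    return [chosen[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # higher rank wins ties; '' > 'A' > 'B' ... so earlier altloc ids win
    if not altloc:
        return 1.0
    return -ord(altloc)


def read_structure(path: str | Path) -> StructureFrame:
    """Read a single-model PDB file into a topology plus one frame.

    Altlocs are resolved (highest occupancy, then altloc order), HELIX
    records are exposed as candidate :class:`HelixDefinition` objects.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError(f"{path} contains no models")

    model = st[0]
    records = []
    for chain in model:
        for res in chain:
            for atom in res:
                records.append(
                    (
                        Atom(
                            name=atom.name,
                            element=atom.element.name,
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            chain_id=chain.name,
                            altloc=atom.altloc or "",
                            occupancy=atom.occ,
                        ),
                        (atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    if not records:
        raise EmptyInputError(f"{path} contains no atoms")

    records = _resolve_altlocs(records)
    atoms = [replace(a, altloc="") for a, _ in records]
    coords = np.array([xyz for _, xyz in records], dtype=float)

    helices = []
    for i, helix in enumerate(st.helices):
        helices.append(
            HelixDefinition(
                name=f"HELIX{i + 1}",
                chain_id=helix.start.chain_name,
                first_residue=helix.start.res_id.seqid.num,
                last_residue=helix.end.res_id.seqid.num,
            )
        )
    return StructureFrame(Topology(atoms), coords, helices)


def write_structure(
    frame: StructureFrame | None,
    path: str | Path,
    *,
    topology: Topology | None = None,
    coordinate_frames: Sequence[np.ndarray] | None = None,
) -> None:
    """Write a single- or multi-model PDB file.

    Either pass a :class:`StructureFrame`, or a topology plus a list of
    coordinate frames (one MODEL per frame).
    """
    import gemmi

    if frame is not None:
        topology = frame.topology
        coordinate_frames = [frame.coordinates]
    if topology is None or coordinate_frames is None:
        raise ValueError("need a StructureFrame or topology+coordinate_frames")

    # group atom indices by chain, then by residue, preserving file order
    chain_order: list[str] = []
    chain_residues: dict[str, list[tuple[tuple[str, int], list[int]]]] = {}
    for i, atom in enumerate(topology.atoms):
        if atom.chain_id not in chain_residues:
            chain_residues[atom.chain_id] = []
            chain_order.append(atom.chain_id)
        residues = chain_residues[atom.chain_id]
        rkey = (atom.residue_name, atom.residue_number)
        if not residues or residues[-1][0] != rkey:
            residues.append((rkey, []))
        residues[-1][1].append(i)

    st = gemmi.Structure()
    st.name = "helixbridge"
    for m, coords in enumerate(coordinate_frames, start=1):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (topology.n_atoms, 3):
            raise TopologyError("coordinate frame does not match topology atom count")
        model = gemmi.Model(m)
        for chain_id in chain_order:
            chain = gemmi.Chain(chain_id)
            for (resname, resnum), atom_ids in chain_residues[chain_id]:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                for i in atom_ids:
                    atom = topology.atoms[i]
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element or "X")
                    ga.occ = atom.occupancy
                    ga.pos = gemmi.Position(*coords[i])
                    res.add_atom(ga)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(Path(path)))


_TIMESTAMPED_FORMATS = {".xtc", ".trr"}


def read_trajectory(
    topology_path: str | Path,
    traj_paths: Sequence[str | Path],
    frame_dt: float | None = None,
) -> TrajectoryEnsemble:
    """Read one or more trajectory files sharing a topology.

    ``frame_dt`` (ns) assigns frame times for formats without reliable
    time stamps (DCD, multi-model PDB); XTC/TRR native times take
    precedence and ``frame_dt`` is ignored for them.
    """
    import MDAnalysis as mda

    if not traj_paths:
        raise EmptyInputError("no trajectory files given")
    topology_path = Path(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        topology = _topology_from_universe(mda.Universe(str(topology_path)))

    replicas = []
    for traj in traj_paths:
        traj = Path(traj)
        native_time = traj.suffix.lower() in _TIMESTAMPED_FORMATS
        if not native_time and frame_dt is None:
            raise ConfigurationError(
                f"{traj.name}: format has no time stamps, frame_dt (ns) is required"
            )
        try:
            with warnings.catch_warnings():
                # placeholder CRYST1 records in generated PDBs are expected
                warnings.simplefilter("ignore", UserWarning)
                uni = mda.Universe(str(topology_path), str(traj))
        except IndexError as exc:
            # MDAnalysis trips an IndexError when the trajectory carries
            # more atoms than the topology
            raise TopologyError(
                f"{traj.name}: atom count does not match topology"
            ) from exc
        except (OSError, ValueError) as exc:
            raise FormatError(f"cannot read trajectory {traj}: {exc}") from exc
        if uni.atoms.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"{traj.name}: {uni.atoms.n_atoms} atoms vs topology {topology.n_atoms}"
            )
        coords = []
        times = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MDA reader chatter on dt guessing
            for i, ts in enumerate(uni.trajectory):
                coords.append(ts.positions.astype(float).copy())
                if native_time:
                    times.append(float(ts.time) / 1000.0)  # ps -> ns
                else:
                    times.append(i * frame_dt)
        if not coords:
            raise EmptyInputError(f"{traj.name}: trajectory has no frames")
        replicas.append(Replica(np.array(times), np.array(coords)))
    return TrajectoryEnsemble(topology, replicas)


def _topology_from_universe(uni) -> Topology:
    atoms = []
    n = uni.atoms.n_atoms
    names = uni.atoms.names
    resnames = uni.atoms.resnames
    resids = uni.atoms.resids
    try:
        chains = uni.atoms.chainIDs
    except AttributeError:
        try:
            chains = uni.atoms.segids
        except AttributeError:
            chains = ["A"] * n
    try:
        elements = uni.atoms.elements
    except AttributeError:
        elements = ["" for _ in range(n)]
    try:
        altlocs = uni.atoms.altLocs
    except AttributeError:
        altlocs = ["" for _ in range(n)]
    if any(str(a).strip() for a in altlocs):
        raise FormatError(
            "trajectory topology contains alternate locations; resolve altlocs "
            "(e.g. via read_structure + write_structure) before trajectory analysis"
        )
    for i in range(n):
        chain = str(chains[i]).strip() or "A"
        atoms.append(
            Atom(
                name=str(names[i]),
                element=str(elements[i]).strip(),
                residue_name=str(resnames[i]),
                residue_number=int(resids[i]),
                chain_id=chain,
            )
        )
    return Topology(atoms)


def select_charged_atoms(
    topology: Topology, residue_key: tuple[str, int]
) -> tuple[list[int], list[str]]:
    """Return (atom indices, missing atom names) of a residue's charged set.

    Arg -> NE, NH1, NH2; Lys -> NZ; Asp -> OD1, OD2; Glu -> OE1, OE2.
    Residues outside these four types raise
    :class:`~helixbridge.errors.UnsupportedResidueError`; atoms missing
    from the structure are reported so callers can flag the residue as
    unusable rather than silently computing on a partial set.
    """
    res = topology.residue(*residue_key)
    try:
        wanted = CHARGED_SIDECHAIN_ATOMS[res.residue_name]
    except KeyError:
        raise UnsupportedResidueError(
            f"{res.residue_name} {residue_key} has no charged side-chain atom set"
        ) from None
    indices = []
    missing = []
    for name in wanted:
        idx = res.atom_index.get(name)
        if idx is None:
            missing.append(name)
        else:
            indices.append(idx)
    return indices, missing


def equilibration_filter(
    ensemble: TrajectoryEnsemble, config: AnalysisConfig
) -> TrajectoryEnsemble:
    """Drop all frames earlier than ``config.equilibration_ns`` (and apply stride).

    Replicas emptied by the cut are dropped with a warning; if nothing
    remains anywhere the analysis is empty and an error is raised.
    The operation is idempotent and preserves frame order.
    """
    kept = []
    for i, rep in enumerate(ensemble.replicas):
        mask = rep.times >= config.equilibration_ns
        times = rep.times[mask][:: config.stride]
        coords = rep.coordinates[mask][:: config.stride]
        if len(times) == 0:
            warnings.warn(
                f"replica {i}: all frames fall before the {config.equilibration_ns} ns "
                "equilibration cut; replica dropped",
                stacklevel=2,
            )
            continue
        kept.append(Replica(times, coords))
    if not kept:
        raise EmptyAnalysisError(
            f"equilibration cut at {config.equilibration_ns} ns removed every frame"
        )
    return TrajectoryEnsemble(ensemble.topology, kept)


def load_config(
    path: str | Path,
) -> tuple[AnalysisConfig, list[HelixDefinition], list[ResiduePair]]:
    """Load an analysis YAML: AnalysisConfig keys + helices + residue pairs.

    Example::

        equilibration_ns: 30
        contact_cutoff: 3.5
        helices:
          - {name: H9, chain_id: A, first_residue: 352, last_residue: 370}
        pairs:
          - {acidic: [A, 340], basic: [A, 387], label: R387-D340}
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" (line {mark.line + 1})" if mark is not None else ""
        raise ConfigurationError(f"invalid YAML in {path}{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level of config must be a mapping")

    helices = [
        HelixDefinition(
            name=str(h["name"]),
            chain_id=str(h.get("chain_id", "A")),
            first_residue=int(h["first_residue"]),
            last_residue=int(h["last_residue"]),
        )
        for h in raw.pop("helices", [])
    ]
    pairs = []
    for p in raw.pop("pairs", []):
        ac, bc = p["acidic"], p["basic"]
        pairs.append(
            ResiduePair(
                acidic_chain=str(ac[0]),
                acidic_residue=int(ac[1]),
                basic_chain=str(bc[0]),
                basic_residue=int(bc[1]),
                label=str(p.get("label", "")),
            )
        )
    raw.pop("helix_pairs", None)
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        config = AnalysisConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
    return config, helices, pairs
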