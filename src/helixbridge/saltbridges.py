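"""Electrostatic-contact statistics and charged side-chain distance pools.

A salt-bridge *contact* in a frame means the minimum distance between any
side-chain oxygen of the acidic residue (Asp OD1/OD2, Glu OE1/OE2) and
any side-chain nitrogen of the basic residue (Arg NE/NH1/NH2, Lys NZ) is
at or below the cutoff (3.5 Å by default, boundary inclusive).  The
contact probability of a pair is the fraction of analysed frames in
contact, pooled over replicas.

Distance *pools* are a different summary: every O–N atom-pair distance of
the pair, pooled over frames and replicas, from which histograms and
"fraction below threshold" statistics are derived.  Contacts use the
per-frame minimum; pools use all atom pairs — the two are deliberately
kept apart.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyAnalysisError, PipelineError, UnusableResidueError
from .io_core import (
    ACIDIC_RESIDUES,
    BASIC_RESIDUES,
    AnalysisConfig,
    ResiduePair,
    StructureFrame,
    Topology,
    TrajectoryEnsemble,
    select_charged_atoms,
)


@dataclass
class ContactResult:
    """Contact statistic of one residue pair over an ensemble."""

    pair: ResiduePair
    n_frames: int
    n_contact_frames: int
    #: (n_frames, n_contact_frames) per replica, same pooling order
    per_replica: list[tuple[int, int]] = field(default_factory=list)

    @property
    def probability(self) -> float:
        return self.n_contact_frames / self.n_frames


@dataclass
class DistancePool:
    """All side-chain O–N distances of one pair pooled over frames/replicas."""

    pair: ResiduePair
    distances: np.ndarray
    threshold: float
    lower_threshold: float = 2.0

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def fraction_below(self) -> float:
        """Fraction of pooled distances below the configured threshold."""
        return float(np.mean(self.distances < self.threshold))

    @property
    def fraction_between(self) -> float:
        """Fraction of pooled distances in [lower_threshold, threshold)."""
        return float(
            np.mean(
                (self.distances >= self.lower_threshold)
                & (self.distances < self.threshold)
            )
        )

    def histogram(self, bin_width: float = 0.2) -> pd.DataFrame:
        """Binned distance counts and densities (TSV-ready)."""
        lo = 0.0
        hi = float(np.max(self.distances)) + bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(self.distances, bins=edges)
        density = counts / (counts.sum() * bin_width)
        return pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bin_right": edges[1:],
                "count": counts,
                "density": density,
            }
        )


def _charged_indices(topology: Topology, pair: ResiduePair) -> tuple[list[int], list[int]]:
    """Atom indices of the acidic O set and basic N set, validated complete."""
    acid = topology.residue(*pair.acidic_key)
    base = topology.residue(*pair.basic_key)
    if acid.residue_name not in ACIDIC_RESIDUES:
        raise UnusableResidueError(
            f"{pair.display()}: {acid.residue_name} is not an acidic residue"
        )
    if base.residue_name not in BASIC_RESIDUES:
        raise UnusableResidueError(
            f"{pair.display()}: {base.residue_name} is not a basic residue"
        )
    o_idx, o_missing = select_charged_atoms(topology, pair.acidic_key)
    n_idx, n_missing = select_charged_atoms(topology, pair.basic_key)
    if o_missing or n_missing:
        raise UnusableResidueError(
            f"{pair.display()}: incomplete charged side chains "
            f"(missing {o_missing + n_missing}); residue unusable for contact analysis"
        )
    return o_idx, n_idx


def _pairwise_distances(frame: np.ndarray, o_idx, n_idx) -> np.ndarray:
    """All O–N Euclidean distances in one frame, flattened."""
    diff = frame[np.asarray(o_idx)][:, None, :] - frame[np.asarray(n_idx)][None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1)).ravel()


def pair_min_distance(
    frame: np.ndarray, pair: ResiduePair, topology: Topology
) -> float:
    """Minimum side-chain O–N distance (Å) of a residue pair in one frame."""
    o_idx, n_idx = _charged_indices(topology, pair)
    return float(np.min(_pairwise_distances(frame, o_idx, n_idx)))


def is_contact(distance: float, config: AnalysisConfig) -> bool:
    """Whether a distance satisfies the contact criterion (boundary inclusive)."""
    if distance < 0:
        raise PipelineError(f"negative distance {distance}")
    return distance <= config.contact_cutoff


def contact_probability(
    ensemble: TrajectoryEnsemble, pair: ResiduePair, config: AnalysisConfig
) -> ContactResult:
    """Fraction of frames in which the pair forms an electrostatic contact.

    Frames are pooled across replicas; the caller is expected to have
    applied the equilibration filter already.  Per-replica counts are
    retained for diagnostics.
    """
    o_idx, n_idx = _charged_indices(ensemble.topology, pair)
    if ensemble.n_frames == 0:
        raise EmptyAnalysisError("no frames to analyse")
    per_replica = []
    n_total = 0
    n_contact = 0
    for rep in ensemble.replicas:
        rep_contact = 0
        for frame in rep.coordinates:
            dmin = np.min(_pairwise_distances(frame, o_idx, n_idx))
            if dmin <= config.contact_cutoff:
                rep_contact += 1
        per_replica.append((rep.n_frames, rep_contact))
        n_total += rep.n_frames
        n_contact += rep_contact
    return ContactResult(pair, n_total, n_contact, per_replica)


def network_total(results: list[ContactResult | float]) -> float:
    """Arithmetic sum of contact probabilities over a pair network."""
    if not results:
        raise EmptyAnalysisError("network_total needs at least one result")
    total = 0.0
    for r in results:
        total += r.probability if isinstance(r, ContactResult) else float(r)
    return total


def distance_pool(
    ensemble: TrajectoryEnsemble, pair: ResiduePair, config: AnalysisConfig
) -> DistancePool:
    """Pool every side-chain O–N distance of the pair over frames and replicas."""
    o_idx, n_idx = _charged_indices(ensemble.topology, pair)
    if ensemble.n_frames == 0:
        raise EmptyAnalysisError("no frames to analyse")
    chunks = [
        _pairwise_distances(frame, o_idx, n_idx)
        for rep in ensemble.replicas
        for frame in rep.coordinates
    ]
    return DistancePool(pair, np.concatenate(chunks), config.hist_fraction_threshold)


def static_salt_bridges(
    structure: StructureFrame,
    config: AnalysisConfig,
    pairs: list[ResiduePair] | None = None,
) -> list[tuple[ResiduePair, float, bool]]:
    """Detect salt bridges in a single structure (e.g. a crystal model).

    Enumerates all acidic x basic residue pairs with complete charged
    side chains (or a configured pair list) and reports
    (pair, min O–N distance, contact flag).  Pairs in contact come first,
    sorted by distance.
    """
    topo = structure.topology
    if pairs is None:
        acidic = [
            r.key for r in topo.residues.values() if r.residue_name in ACIDIC_RESIDUES
        ]
        basic = [
            r.key for r in topo.residues.values() if r.residue_name in BASIC_RESIDUES
        ]
        if not acidic or not basic:
            warnings.warn("structure has no charged residue pairs", stacklevel=2)
            return []
        pairs = [
            ResiduePair(a[0], a[1], b[0], b[1])
            for a, b in itertools.product(acidic, basic)
        ]
    out = []
    for pair in pairs:
        try:
            d = pair_min_distance(structure.coordinates, pair, topo)
        except UnusableResidueError:
            continue
        out.append((pair, d, d <= config.contact_cutoff))
    out.sort(key=lambda item: (not item[2], item[1]))
    return out


def contacts_to_frame(results: list[ContactResult]) -> pd.DataFrame:
    """Tabulate contact results (CSV-ready, one row per pair)."""
    return pd.DataFrame(
        {
            "pair": [r.pair.display() for r in results],
            "n_frames": [r.n_frames for r in results],
            "n_contacts": [r.n_contact_frames for r in results],
            "probability": [r.probability for r in results],
        }
    )


def pools_to_frame(pools: list[DistancePool]) -> pd.DataFrame:
    """Tabulate distance-pool summaries (CSV-ready, one row per pair)."""
    return pd.DataFrame(
        {
            "pair": [p.pair.display() for p in pools],
            "n_distances": [len(p.distances) for p in pools],
            "mean": [p.mean for p in pools],
            "fraction_below": [p.fraction_below for p in pools],
            "fraction_between": [p.fraction_between for p in pools],
        }
    )
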