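"""Classification of four-oscillator CPG spike patterns into dynamical modes.

A settled pattern of the four pulse-coupled oscillators is one of five base
modes: in-phase (IP), triplet-singlet ('3+1', T1), anti-phase (AP),
doublet-singlet-singlet ('2+1+1', DSS) and splay (S).  Counting oscillator
permutations there are exactly 26 sub-modes: 1 IP + 4 T1 + 3 AP + 12 DSS +
6 S.  A sub-mode is represented here as the cyclic firing order of its
clusters, canonicalised to start with the cluster containing oscillator 1;
e.g. ``AP(1,3+2,4)`` is the anti-phase mode with clusters {1,3} and {2,4}.

Classification is a circular least-squares match of the measured per-
oscillator phase offsets against the canonical offsets of all 26 labels,
optimising over a global rotation, so it is invariant under time translation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .network_sim import SpikeTrain

__all__ = [
    "ModeLabel",
    "PhasePattern",
    "ClusterPartition",
    "Classification",
    "IRREGULAR",
    "PeriodError",
    "all_mode_labels",
    "canonical_phases",
    "global_period",
    "phase_pattern",
    "cluster_partition",
    "classify",
    "classify_detail",
    "parse_label",
]

N_OSC = 4
BASE_OF_SIZE_SIGNATURE = {
    (4,): "IP",
    (3, 1): "T1",
    (2, 2): "AP",
    (2, 1, 1): "DSS",
    (1, 1, 1, 1): "S",
}


class PeriodError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModeLabel:
    """A CPG sub-mode: base mode plus the cyclic firing order of clusters.

    ``clusters`` lists the clusters in firing order starting from the one
    containing oscillator 1 (oscillators are numbered from 1); each cluster
    is a sorted tuple of oscillator indices.
    """

    base: str
    clusters: tuple[tuple[int, ...], ...] = ()

    @staticmethod
    def from_clusters(clusters) -> "ModeLabel":
        blocks = [tuple(sorted(c)) for c in clusters]
        sizes = tuple(sorted((len(b) for b in blocks), reverse=True))
        base = BASE_OF_SIZE_SIGNATURE.get(sizes)
        if base is None or sum(sizes) != N_OSC:
            raise ValueError(f"invalid cluster structure {clusters}")
        k = next(i for i, b in enumerate(blocks) if 1 in b)
        rotated = tuple(blocks[k:] + blocks[:k])
        return ModeLabel(base=base, clusters=rotated)

    @property
    def is_irregular(self) -> bool:
        return self.base == "irregular"

    def __str__(self) -> str:
        if self.is_irregular:
            return "irregular"
        if self.base == "IP":
            return "IP"
        inner = "+".join(",".join(str(i) for i in c) for c in self.clusters)
        return f"{self.base}({inner})"


IRREGULAR = ModeLabel(base="irregular")


def parse_label(text: str) -> ModeLabel:
    """Parse labels like ``"AP(1,3+2,4)"`` or ``"IP"`` back into a ModeLabel."""
    text = text.strip()
    if text == "irregular":
        return IRREGULAR
    if text == "IP":
        return ModeLabel.from_clusters([(1, 2, 3, 4)])
    base, _, rest = text.partition("(")
    if not rest.endswith(")"):
        raise ValueError(f"malformed mode label {text!r}")
    clusters = [tuple(int(t) for t in part.split(",")) for part in rest[:-1].split("+")]
    label = ModeLabel.from_clusters(clusters)
    if label.base != base:
        raise ValueError(f"label {text!r} names base {base} but structure is {label.base}")
    return label


def all_mode_labels() -> list[ModeLabel]:
    """Enumerate all 26 sub-modes: 1 IP + 4 T1 + 3 AP + 12 DSS + 6 S."""
    labels = [ModeLabel.from_clusters([(1, 2, 3, 4)])]
    osc = (1, 2, 3, 4)
    # T1: choice of the singlet
    for s in osc:
        triplet = tuple(i for i in osc if i != s)
        labels.append(ModeLabel.from_clusters([triplet, (s,)]))
    # AP: pairings of 1 with one partner
    for partner in (2, 3, 4):
        a = (1, partner)
        b = tuple(i for i in osc if i not in a)
        labels.append(ModeLabel.from_clusters([a, b]))
    # DSS: doublet choice x order of the two singlets
    for doublet in itertools.combinations(osc, 2):
        rest = [i for i in osc if i not in doublet]
        for s1, s2 in itertools.permutations(rest):
            labels.append(ModeLabel.from_clusters([doublet, (s1,), (s2,)]))
    # S: cyclic firing orders, oscillator 1 first
    for order in itertools.permutations((2, 3, 4)):
        labels.append(ModeLabel.from_clusters([(1,)] + [(i,) for i in order]))
    assert len(labels) == 26
    return labels


@dataclass(frozen=True)
class PhasePattern:
    """Global period and per-oscillator spike-time offsets in [0, T)."""

    T: float
    offsets: tuple[float, ...]


@dataclass(frozen=True)
class ClusterPartition:
    blocks: tuple[tuple[int, ...], ...]
    delta: float


# canonical within-period cluster offsets, as fractions of T
_CLUSTER_FRACTIONS = {
    "IP": (0.0,),
    "T1": (0.0, 0.5),          # nominal anti-phase singlet
    "AP": (0.0, 0.5),
    "DSS": (0.0, 1 / 3, 2 / 3),
    "S": (0.0, 0.25, 0.5, 0.75),
}


def canonical_phases(label: ModeLabel, T: float) -> PhasePattern:
    """Nominal spike-time offsets of a sub-mode at global period ``T``."""
    if label.is_irregular:
        raise ValueError("no canonical phases for the irregular label")
    fracs = _CLUSTER_FRACTIONS[label.base]
    offsets = [0.0] * N_OSC
    for frac, cluster in zip(fracs, label.clusters):
        for i in cluster:
            offsets[i - 1] = frac * T
    return PhasePattern(T=T, offsets=tuple(offsets))


def global_period(trains: SpikeTrain, n_discard: int = 4) -> float:
    """Common per-oscillator period: mean inter-spike interval after
    discarding transients; oscillator means must agree within 1%."""
    means = []
    for nid, ts in trains.trains.items():
        if len(ts) < n_discard + 3:
            raise PeriodError(f"oscillator {nid}: too few spikes ({len(ts)})")
        isi = np.diff(ts)[n_discard:]
        means.append(isi.mean())
    means = np.asarray(means)
    T = float(means.mean())
    if (means.max() - means.min()) > 0.01 * T:
        raise PeriodError(
            f"no common period: per-oscillator means {means} differ by more than 1%"
        )
    return T


def phase_pattern(trains: SpikeTrain, n_discard: int = 4) -> PhasePattern:
    """Circular-mean spike-time offset of each oscillator relative to the first."""
    T = global_period(trains, n_discard=n_discard)
    ids = list(trains.trains)
    angles = []
    for nid in ids:
        ts = trains.trains[nid][n_discard:]
        ang = 2.0 * np.pi * (ts % T) / T
        angles.append(np.angle(np.exp(1j * ang).mean()))
    offsets = [((a - angles[0]) / (2.0 * np.pi)) % 1.0 * T for a in angles]
    return PhasePattern(T=T, offsets=tuple(offsets))


def _circ_dist(a: np.ndarray, T: float) -> np.ndarray:
    """Circular distance of time offsets, in [0, T/2]."""
    d = np.mod(a, T)
    return np.minimum(d, T - d)


def cluster_partition(pattern: PhasePattern, delta: float = 0.05) -> ClusterPartition:
    """Partition oscillators into clusters: i, j share a block iff their
    offset distance is below ``delta * T``, closed transitively."""
    off = np.asarray(pattern.offsets)
    T = pattern.T
    parent = list(range(N_OSC))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(N_OSC):
        for j in range(i + 1, N_OSC):
            if _circ_dist(np.array([off[i] - off[j]]), T)[0] < delta * T:
                parent[find(i)] = find(j)
    blocks: dict[int, list[int]] = {}
    for i in range(N_OSC):
        blocks.setdefault(find(i), []).append(i + 1)
    ordered = sorted((tuple(b) for b in blocks.values()), key=lambda b: b[0])
    return ClusterPartition(blocks=tuple(ordered), delta=delta)


def _match_distance(pattern: PhasePattern, label: ModeLabel) -> float:
    """Largest per-oscillator circular offset error against a label's
    canonical pattern, after optimising the global rotation."""
    canon = canonical_phases(label, pattern.T)
    T = pattern.T
    th = 2.0 * np.pi * np.asarray(pattern.offsets) / T
    ck = 2.0 * np.pi * np.asarray(canon.offsets) / T
    rot = np.angle(np.exp(1j * (th - ck)).mean())
    d = np.angle(np.exp(1j * (th - ck - rot)))
    return float(np.max(np.abs(d)) * T / (2.0 * np.pi))


def classify_detail(trains: SpikeTrain, delta: float = 0.05,
                    radius: float = 0.08, n_discard: int = 4) -> "Classification":
    """Nearest-canonical-pattern classification over all 26 sub-mode labels.

    A pattern farther than ``radius * T`` (per oscillator, after the optimal
    rotation) from every canonical pattern is labelled irregular.
    """
    pattern = phase_pattern(trains, n_discard=n_discard)
    best_label, best_d = IRREGULAR, np.inf
    for label in all_mode_labels():
        d = _match_distance(pattern, label)
        if d < best_d:
            best_label, best_d = label, d
    if best_d > radius * pattern.T:
        best_label = IRREGULAR
    return Classification(label=best_label, pattern=pattern, distance=best_d,
                          delta=delta)


@dataclass(frozen=True)
class Classification:
    label: ModeLabel
    pattern: PhasePattern
    distance: float
    delta: float

    @property
    def T(self) -> float:
        return self.pattern.T


def classify(trains: SpikeTrain, delta: float = 0.05,
             radius: float = 0.08, n_discard: int = 4) -> ModeLabel:
    """Classify spike trains into one of the 26 sub-modes (or 'irregular')."""
    return classify_detail(trains, delta=delta, radius=radius,
                           n_discard=n_discard).label
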