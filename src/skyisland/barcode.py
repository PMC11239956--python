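"""COI barcode analyses: K2P distances, barcode-gap delimitation, networks.

Distance-based species delimitation asks whether a "barcode gap" —
a discontinuity between intraspecific and interspecific pairwise
distances — exists.  Distances use the Kimura two-parameter model with
pairwise deletion (sites with gaps, N, or IUPAC ambiguity in either
sequence are excluded per pair).  Partitioning follows the spirit of the
Automatic Barcode Gap Discovery initial partition: ranked distances are
scanned for the first significant gap beyond each prior on maximum
intraspecific divergence, groups split by single linkage at the gap, one
recursion level applied, and the modal partition across the prior grid
returned.

Haplotype structure is summarized by collapsing identical sequences and
connecting haplotypes in a minimum-spanning network (all tie-equal MST
edges) under a statistical-parsimony connection limit in the
Templeton–Crandall–Sing tradition.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .sequences import SequenceAlignment, UNAMBIGUOUS

__all__ = [
    "DistanceSummary",
    "HaploNetwork",
    "k2p_distance",
    "k2p_matrix",
    "distance_summaries",
    "barcode_gap_partition",
    "collapse_haplotypes",
    "parsimony_connection_limit",
    "parsimony_probabilities",
    "build_parsimony_network",
    "haplotype_network",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


# ----------------------------------------------------------------------
# K2P distances
# ----------------------------------------------------------------------

def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok_a = np.isin(a, list(UNAMBIGUOUS))
    ok_b = np.isin(b, list(UNAMBIGUOUS))
    return ok_a & ok_b


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance with pairwise deletion.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P, Q the proportions of
    transitional and transversional differences among comparable sites.
    Raises on saturation (log argument ≤ 0) or zero comparable sites.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    aa = np.array(list(a.upper()), dtype="U1")
    bb = np.array(list(b.upper()), dtype="U1")
    keep = _comparable(aa, bb)
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    aa, bb = aa[keep], bb[keep]
    diff = aa != bb
    ts = sum(
        1 for x, y in zip(aa[diff], bb[diff]) if frozenset((x, y)) in _TRANSITIONS
    )
    tv = int(diff.sum()) - ts
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise ValueError("K2P distance undefined: substitution saturation")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(aln: SequenceAlignment) -> np.ndarray:
    """Symmetric K2P distance matrix over all sequence pairs."""
    n = aln.n_sequences
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = k2p_distance(aln.sequences[i], aln.sequences[j])
    return D


@dataclass
class DistanceSummary:
    """Pairwise-distance summaries (substitutions/site; percent = 100x)."""

    model: str
    matrix: np.ndarray
    intra_mean: dict[str, float]
    inter_mean: float
    min: float
    max: float

    def intra_mean_percent(self, species: str) -> float:
        return round(100.0 * self.intra_mean[species], 2)

    @property
    def inter_mean_percent(self) -> float:
        return round(100.0 * self.inter_mean, 2)


def distance_summaries(
    aln: SequenceAlignment, matrix: np.ndarray | None = None
) -> DistanceSummary:
    """Arithmetic means of pairwise K2P distances within and between species.

    Species represented by a single sequence get an intra mean of NaN
    (flagged, not an error).
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least two sequences")
    if aln.species is None:
        raise ValueError("species labels are required for distance summaries")
    D = k2p_matrix(aln) if matrix is None else matrix
    species = np.asarray(aln.species)
    labels = list(dict.fromkeys(aln.species))

    intra: dict[str, float] = {}
    for lab in labels:
        idx = np.flatnonzero(species == lab)
        if idx.size < 2:
            intra[lab] = float("nan")
            continue
        pairs = [D[i, j] for i, j in itertools.combinations(idx, 2)]
        intra[lab] = float(np.mean(pairs))

    inter_pairs = [
        D[i, j]
        for i, j in itertools.combinations(range(aln.n_sequences), 2)
        if species[i] != species[j]
    ]
    if len(labels) < 2 or not inter_pairs:
        raise ValueError("inter-specific mean needs at least two species")
    off = D[np.triu_indices(aln.n_sequences, k=1)]
    return DistanceSummary(
        model="K2P",
        matrix=D,
        intra_mean=intra,
        inter_mean=float(np.mean(inter_pairs)),
        min=float(off.min()),
        max=float(off.max()),
    )


# ----------------------------------------------------------------------
# Barcode-gap partitioning
# ----------------------------------------------------------------------

def _single_linkage_groups(D: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the graph linking pairs with d <= threshold."""
    n = D.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if D[i, j] <= threshold:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _first_gap_threshold(
    dists: np.ndarray, prior: float, relative_gap_width: float
) -> float | None:
    """First significant gap in the ranked distances beyond the prior.

    A gap between consecutive ranked distances d_i < d_{i+1} (with
    d_{i+1} > prior) is significant when its width exceeds
    ``relative_gap_width * max(d_i, prior)`` — i.e. the jump is large
    relative to the distance scale already reached.  Returns the midpoint
    threshold, or None when no gap qualifies.
    """
    ds = np.unique(dists)
    for i in range(len(ds) - 1):
        lo, hi = ds[i], ds[i + 1]
        if hi <= prior:
            continue
        if (hi - lo) > relative_gap_width * max(lo, prior):
            return (lo + hi) / 2.0
    return None


def _partition_once(
    D: np.ndarray, idx: list[int], prior: float, relative_gap_width: float
) -> list[list[int]]:
    sub = D[np.ix_(idx, idx)]
    pair_d = sub[np.triu_indices(len(idx), k=1)]
    if pair_d.size == 0:
        return [list(idx)]
    thr = _first_gap_threshold(pair_d, prior, relative_gap_width)
    if thr is None:
        return [list(idx)]
    groups = _single_linkage_groups(sub, thr)
    return [[idx[i] for i in grp] for grp in groups]


def barcode_gap_partition(
    matrix: np.ndarray,
    prior_max_intra: np.ndarray | None = None,
    relative_gap_width: float = 1.5,
) -> dict:
    """ABGD-style initial partition of sequences from a distance matrix.

    For each prior maximum intraspecific distance P on a log grid
    (default 0.001–0.1, 10 steps, the tool's customary defaults), ranked
    distances are scanned for the first significant gap beyond P, groups
    are split by single linkage at the gap threshold, and the split is
    applied once more inside each group (one recursion level).  The
    consensus is the modal partition across the prior grid.  A single
    group is a valid outcome, not an error.

    Returns a dict with ``partitions_by_prior``, ``n_groups_by_prior`` and
    ``consensus`` (list of index groups).
    """
    D = np.asarray(matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if prior_max_intra is None:
        prior_max_intra = np.geomspace(0.001, 0.1, 10)

    partitions: dict[float, list[list[int]]] = {}
    for prior in prior_max_intra:
        groups = _partition_once(D, list(range(n)), prior, relative_gap_width)
        refined: list[list[int]] = []
        for grp in groups:
            if len(grp) > 2 and len(groups) > 1:
                refined.extend(_partition_once(D, grp, prior, relative_gap_width))
            else:
                refined.append(grp)
        partitions[float(prior)] = sorted(
            (sorted(g) for g in refined), key=lambda g: g[0]
        )

    keys = [tuple(tuple(g) for g in p) for p in partitions.values()]
    counts: dict[tuple, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    consensus_key = max(counts, key=lambda k: (counts[k], -len(k)))
    consensus = [list(g) for g in consensus_key]
    return {
        "partitions_by_prior": partitions,
        "n_groups_by_prior": {p: len(g) for p, g in partitions.items()},
        "consensus": consensus,
        "n_groups": len(consensus),
    }


# ----------------------------------------------------------------------
# Haplotypes and parsimony networks
# ----------------------------------------------------------------------

@dataclass
class Haplotype:
    sequence: str
    frequency: int
    member_ids: list[str]
    species_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class HaploNetwork:
    """Haplotypes plus mutational-step edges under a parsimony limit."""

    haplotypes: list[Haplotype]
    edges: list[tuple[int, int, int]]  # (i, j, steps)
    connection_limit: int | None = None

    def to_networkx(self):
        """Network as a :class:`networkx.Graph` (for GraphML export etc.)."""
        import networkx as nx

        G = nx.Graph()
        for k, hap in enumerate(self.haplotypes):
            G.add_node(
                k,
                frequency=hap.frequency,
                members=",".join(hap.member_ids),
                species=",".join(
                    f"{s}:{n}" for s, n in sorted(hap.species_counts.items())
                ),
            )
        for i, j, steps in self.edges:
            G.add_edge(i, j, steps=steps)
        return G

    @property
    def n_components(self) -> int:
        n = len(self.haplotypes)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j, _ in self.edges:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        return len({find(i) for i in range(n)})


def collapse_haplotypes(aln: SequenceAlignment) -> HaploNetwork:
    """Collapse identical sequences into haplotypes (exact string match).

    Ambiguity codes are NOT treated as wildcards: two sequences collapse
    only if they are identical character for character.  Haplotype
    frequencies conserve the number of input sequences.
    """
    if aln.n_sequences < 1:
        raise ValueError("need at least one sequence")
    order: dict[str, Haplotype] = {}
    for i, seq in enumerate(aln.sequences):
        hap = order.get(seq)
        if hap is None:
            hap = Haplotype(sequence=seq, frequency=0, member_ids=[])
            order[seq] = hap
        hap.frequency += 1
        hap.member_ids.append(aln.ids[i])
        if aln.species is not None:
            sp = aln.species[i]
            hap.species_counts[sp] = hap.species_counts.get(sp, 0) + 1
    return HaploNetwork(haplotypes=list(order.values()), edges=[])


def parsimony_probabilities(seq_len: int, max_steps: int | None = None) -> np.ndarray:
    """P(parsimony | j observed differences) for j = 0 .. max_steps.

    Model: per-site substitution counts are independent Poisson under
    Jukes–Cantor visibility; the per-site rate is estimated from the
    observed proportion of differing sites (the JC inversion, solved by
    the model's own fixed point), and parsimony means no site was hit more
    than once.  With p = j/m, λ = -3/4 ln(1 - 4p/3):

        P_j = (λ e^{-λ} / p)^j · (e^{-λ} / (1 - p))^{m - j}
    """
    m = seq_len
    if m < 1:
        raise ValueError("seq_len must be >= 1")
    if max_steps is None:
        max_steps = m
    js = np.arange(0, max_steps + 1)
    out = np.empty(js.size)
    out[0] = 1.0
    for idx, j in enumerate(js[1:], start=1):
        p = j / m
        if p >= 0.75:
            out[idx] = 0.0
            continue
        lam = -0.75 * math.log1p(-4.0 * p / 3.0)
        log_p = j * (math.log(lam) - lam - math.log(p)) + (m - j) * (
            -lam - math.log1p(-p)
        )
        out[idx] = math.exp(log_p)
    return out


def parsimony_connection_limit(
    seq_len: int, confidence: float = 0.95
) -> tuple[int, np.ndarray]:
    """Largest step count whose parsimony probability exceeds ``confidence``.

    Returns (limit, probability table).  The probability is non-increasing
    in the number of steps, so the limit is the last index above the
    confidence level.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    probs = parsimony_probabilities(seq_len)
    above = np.flatnonzero(probs > confidence)
    return int(above.max()), probs


def _hamming_steps(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def build_parsimony_network(
    nodes: HaploNetwork,
    distances: np.ndarray | None = None,
    limit: int | None = None,
) -> HaploNetwork:
    """Minimum-spanning network over haplotypes under the step limit.

    Includes every edge that belongs to at least one minimum spanning
    tree (the classic cycle criterion: (u, v) with weight w is MST-usable
    iff u and v are disconnected among edges strictly lighter than w),
    restricted to edges with step counts ≤ limit.  Disconnected
    components remain separate.
    """
    haps = nodes.haplotypes
    n = len(haps)
    if distances is None:
        distances = np.zeros((n, n), dtype=int)
        for i, j in itertools.combinations(range(n), 2):
            distances[i, j] = distances[j, i] = _hamming_steps(
                haps[i].sequence, haps[j].sequence
            )
    D = np.asarray(distances)

    candidates = [
        (int(D[i, j]), i, j)
        for i, j in itertools.combinations(range(n), 2)
        if limit is None or D[i, j] <= limit
    ]
    candidates.sort()

    edges: list[tuple[int, int, int]] = []
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for w, batch in itertools.groupby(candidates, key=lambda e: e[0]):
        batch = list(batch)
        # an equal-weight edge is MST-usable iff its ends are in different
        # components of the strictly-lighter subgraph
        for _, i, j in batch:
            if find(i) != find(j):
                edges.append((i, j, w))
        for _, i, j in batch:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

    return HaploNetwork(haplotypes=haps, edges=edges, connection_limit=limit)


def haplotype_network(
    aln: SequenceAlignment, confidence: float = 0.95
) -> HaploNetwork:
    """Collapse haplotypes and connect them under the 95% parsimony limit."""
    nodes = collapse_haplotypes(aln)
    limit, _ = parsimony_connection_limit(aln.length, confidence)
    return build_parsimony_network(nodes, limit=limit)
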