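"""Pairwise model distances, group distances, distance-profile
correlations, and neighbor-joining trees.

Distances are in expected substitutions per site. Supported models:

* ``p`` — raw proportion of mismatching sites;
* ``jc69`` — Jukes-Cantor closed form, d = -(3/4) ln(1 - 4p/3);
* ``k80`` — Kimura two-parameter closed form on transition/transversion
  proportions;
* ``gtr`` — maximum-likelihood branch length under a general
  time-reversible rate matrix whose stationary frequencies default to the
  empirical base frequencies of the pair and whose exchangeabilities
  default to estimates from the pair's symmetrised divergence matrix;
  the likelihood is maximised in one dimension through the matrix
  exponential (eigendecomposition of the symmetrised generator).

Sites with a gap or ambiguous base in either row are excluded pair by
pair (pairwise deletion). Distances beyond a model's saturation bound
raise :class:`~dendromito.errors.SaturationError`; matrix builders record
such pairs as NaN with an explicit ``saturated`` set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DendromitoError, SaturationError

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

MODELS = ("p", "jc69", "k80", "gtr")


def _site_counts(row_a: str, row_b: str) -> np.ndarray:
    """4x4 divergence count matrix over pairwise-valid sites."""
    if len(row_a) != len(row_b):
        raise DendromitoError("rows differ in length")
    a = np.frombuffer(row_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.upper().encode(), dtype=np.uint8)
    codes = np.full(256, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        codes[ord(base)] = i
    ia, ib = codes[a], codes[b]
    valid = (ia >= 0) & (ib >= 0)
    counts = np.zeros((4, 4))
    np.add.at(counts, (ia[valid], ib[valid]), 1.0)
    return counts


def _jc69(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 3/4: JC69 saturated")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _k80(counts: np.ndarray) -> float:
    n = counts.sum()
    transitions = counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1]
    mismatches = n - np.trace(counts)
    P = transitions / n
    Q = (mismatches - transitions) / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("K80 saturated (log argument <= 0)")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def _gtr_generator(
    freqs: np.ndarray, rates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled GTR generator Q (mean rate 1) and its eigendecomposition
    via the symmetrised form diag(sqrt(pi)) Q diag(1/sqrt(pi))."""
    R = np.zeros((4, 4))
    iu = np.triu_indices(4, k=1)
    R[iu] = rates
    R = R + R.T
    Q = R * freqs[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(freqs, np.diag(Q))
    if mu <= 0:
        raise DendromitoError("degenerate GTR generator")
    Q /= mu
    sq = np.sqrt(freqs)
    B = (sq[:, None] * Q) / sq[None, :]
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    return Q, eigval, eigvec


def _gtr_transition(
    t: float, freqs: np.ndarray, eigval: np.ndarray, eigvec: np.ndarray
) -> np.ndarray:
    sq = np.sqrt(freqs)
    expd = eigvec @ np.diag(np.exp(eigval * t)) @ eigvec.T
    P = (expd / sq[:, None]) * sq[None, :]
    return np.clip(P, 1e-300, None)


_SATURATION_T = 20.0


def _gtr_ml_distance(
    counts: np.ndarray,
    freqs: Optional[np.ndarray],
    rates: Optional[np.ndarray],
) -> float:
    n = counts.sum()
    if n == 0:
        raise DendromitoError("zero valid sites")
    if n == np.trace(counts):
        return 0.0
    sym = (counts + counts.T) / 2.0
    if freqs is None:
        freqs = sym.sum(axis=1) / n
        freqs = np.clip(freqs, 1e-9, None)
        freqs /= freqs.sum()
    else:
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
    if rates is None:
        iu = np.triu_indices(4, k=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = sym[iu] / (freqs[iu[0]] * freqs[iu[1]])
        est = np.where(np.isfinite(est) & (est > 0), est, 1e-6)
        rates = est / est.mean()
    else:
        rates = np.asarray(rates, dtype=float)
    _, eigval, eigvec = _gtr_generator(freqs, rates)
    logpi = np.log(freqs)

    def neg_loglik(t: float) -> float:
        P = _gtr_transition(t, freqs, eigval, eigvec)
        return -float(np.sum(counts * (logpi[:, None] + np.log(P))))

    res = minimize_scalar(
        neg_loglik,
        bounds=(1e-9, _SATURATION_T),
        method="bounded",
        options={"xatol": 1e-10},
    )
    d = float(res.x)
    if d > _SATURATION_T - 1e-2:
        raise SaturationError("GTR optimisation hit the saturation bound")
    return d


def pairwise_distance(
    row_a: str,
    row_b: str,
    model: str = "gtr",
    freqs: Optional[Sequence[float]] = None,
    rates: Optional[Sequence[float]] = None,
) -> float:
    """Model distance between two aligned rows (pairwise deletion).

    ``freqs`` (A,C,G,T) and ``rates`` (AC,AG,AT,CG,CT,GT exchangeabilities)
    override the per-pair empirical estimates for the GTR model.
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    counts = _site_counts(row_a, row_b)
    n = counts.sum()
    if n == 0:
        raise DendromitoError("zero valid sites in pair")
    p = float((n - np.trace(counts)) / n)
    if model == "p":
        return p
    if model == "jc69":
        return float(_jc69(p))
    if model == "k80":
        return float(_k80(counts))
    return _gtr_ml_distance(counts, freqs, rates)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with explicit saturation flags."""

    ids: list[str]
    matrix: np.ndarray
    model: str
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class CorrelationMatrix:
    """Pearson correlations between taxa's distance profiles."""

    ids: list[str]
    matrix: np.ndarray
    undefined: set[tuple[str, str]] = field(default_factory=set)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def distance_matrix(
    rows: Mapping[str, str],
    model: str = "gtr",
    freqs: Optional[Sequence[float]] = None,
    rates: Optional[Sequence[float]] = None,
) -> DistanceMatrix:
    """All-pairs :func:`pairwise_distance`; saturated pairs become NaN and
    are listed in ``saturated``."""
    if hasattr(rows, "rows"):  # accept a ConcatenatedMatrix transparently
        rows = rows.rows
    ids = list(rows)
    n = len(ids)
    mat = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pairwise_distance(
                    rows[ids[i]], rows[ids[j]], model, freqs, rates
                )
            except SaturationError:
                d = np.nan
                saturated.add((ids[i], ids[j]))
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids, mat, model.lower(), saturated)


def group_distance(
    dm: DistanceMatrix,
    groups: Mapping[str, Sequence[str]],
    linkage: str = "mean",
) -> DistanceMatrix:
    """Collapse taxa into named groups.

    Between-group distance is the mean (or min/max by ``linkage``) of all
    between-member pairwise distances; within-group values are ignored.
    """
    reducers = {"mean": np.mean, "min": np.min, "max": np.max}
    if linkage not in reducers:
        raise ValueError(f"unknown linkage {linkage!r}")
    members = {}
    for gname, taxa in groups.items():
        taxa = list(taxa)
        if not taxa:
            raise DendromitoError(f"group {gname!r} is empty")
        missing = [t for t in taxa if t not in dm.ids]
        if missing:
            raise DendromitoError(f"group {gname!r}: unknown taxa {missing}")
        members[gname] = taxa
    overlap = [
        t
        for i, (g1, t1) in enumerate(members.items())
        for g2, t2 in list(members.items())[i + 1 :]
        for t in t1
        if t in t2
    ]
    if overlap:
        raise DendromitoError(f"groups overlap on {sorted(set(overlap))}")
    gnames = list(members)
    out = np.zeros((len(gnames), len(gnames)))
    for i, ga in enumerate(gnames):
        for j in range(i + 1, len(gnames)):
            gb = gnames[j]
            vals = [
                dm.get(a, b) for a in members[ga] for b in members[gb]
            ]
            out[i, j] = out[j, i] = reducers[linkage](vals)
    return DistanceMatrix(gnames, out, dm.model)


def row_correlation(dm: DistanceMatrix) -> CorrelationMatrix:
    """Correlation of distance profiles.

    Entry (i, j) is the Pearson correlation between the distance profiles
    of taxa i and j taken over all other taxa k not in {i, j}, so each
    taxon's self-distance and the focal pair's mutual distance never enter
    the correlation. Needs at least 4 taxa; zero-variance profiles give
    NaN entries flagged in ``undefined``.
    """
    n = dm.n
    if n < 4:
        raise DendromitoError("row correlation needs >= 4 taxa")
    out = np.eye(n)
    undefined: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            ks = [k for k in range(n) if k not in (i, j)]
            xi = dm.matrix[i, ks]
            xj = dm.matrix[j, ks]
            if np.std(xi) == 0 or np.std(xj) == 0:
                out[i, j] = out[j, i] = np.nan
                undefined.add((dm.ids[i], dm.ids[j]))
            else:
                r = np.corrcoef(xi, xj)[0, 1]
                out[i, j] = out[j, i] = r
    return CorrelationMatrix(list(dm.ids), out, undefined)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei agglomeration.

    Deterministic: among minimal-Q pairs, the lexicographically smallest
    pair of cluster labels wins (a cluster is labelled by its smallest
    leaf). Negative branch-length estimates are clamped to zero. Raises
    on saturated (non-finite) entries, advising a different model.
    """
    if dm.n < 3:
        raise DendromitoError("NJ needs >= 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise SaturationError(
            "distance matrix has saturated entries; use a different model"
        )
    labels = list(dm.ids)
    subtrees = {lab: lab for lab in labels}  # label -> newick fragment
    D = {
        (a, b): dm.get(a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }

    def dist(a: str, b: str) -> float:
        return D[(a, b)] if (a, b) in D else D[(b, a)]

    active = sorted(labels)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        va = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        vb = dab - va
        va, vb = max(va, 0.0), max(vb, 0.0)
        new_label = min(a, b)
        new_sub = f"({subtrees[a]}:{va:.10g},{subtrees[b]}:{vb:.10g})"
        newD = {}
        for (x, y), v in D.items():
            if a in (x, y) or b in (x, y):
                continue
            newD[(x, y)] = v
        for c in active:
            if c in (a, b):
                continue
            dc = (dist(a, c) + dist(b, c) - dab) / 2.0
            newD[(new_label, c)] = dc
        D = newD
        active = sorted([c for c in active if c not in (a, b)] + [new_label])
        subtrees[new_label] = new_sub

    a, b, c = active
    va = (dist(a, b) + dist(a, c) - dist(b, c)) / 2.0
    vb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2.0
    vc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2.0
    va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
    newick = (
        f"({subtrees[a]}:{va:.10g},{subtrees[b]}:{vb:.10g},"
        f"{subtrees[c]}:{vc:.10g});"
    )
    return dendropy.Tree.get(data=newick, schema="newick")


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised as the side not
    containing the lexicographically smallest leaf."""
    leaves = sorted(t.label for t in tree.taxon_namespace)
    anchor = leaves[0]
    total = set(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        side = total - below if anchor in below else below
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset(side))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric bipartition count."""
    l1 = {t.label for t in t1.taxon_namespace}
    l2 = {t.label for t in t2.taxon_namespace}
    if l1 != l2:
        raise DendromitoError("trees have different leaf sets")
    s1, s2 = _bipartitions(t1), _bipartitions(t2)
    return len(s1 ^ s2)


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    text = str(path_or_string)
    if "(" in text:
        return dendropy.Tree.get(data=text, schema="newick")
    return dendropy.Tree.get(path=text, schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# tabular / graphical output

def write_matrix_tsv(
    dm: DistanceMatrix | CorrelationMatrix, path: str | Path
) -> None:
    """Square matrix TSV (PHYLIP-compatible ordering)."""
    lines = ["\t" + "\t".join(dm.ids)]
    for i, rid in enumerate(dm.ids):
        cells = "\t".join(f"{v:.6f}" for v in dm.matrix[i])
        lines.append(f"{rid}\t{cells}")
    Path(path).write_text("\n".join(lines) + "\n")


def plot_distance_correlation(
    dm: DistanceMatrix, cm: CorrelationMatrix, path: str | Path
) -> None:
    """Mixed panel: pairwise distances as numbers in the lower triangle,
    correlations as sized/coloured discs in the upper triangle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = dm.n
    fig, ax = plt.subplots(figsize=(0.6 * n + 2, 0.6 * n + 2))
    for i in range(n):
        for j in range(n):
            if i > j:
                ax.text(
                    j, i, f"{dm.matrix[i, j]:.3f}",
                    ha="center", va="center", fontsize=7,
                )
            elif i < j:
                r = cm.matrix[i, j]
                if np.isfinite(r):
                    ax.scatter(
                        j, i, s=250 * abs(r) + 5,
                        c=[r], cmap="RdBu", vmin=-1, vmax=1,
                    )
    ax.set_xticks(range(n), dm.ids, rotation=90, fontsize=7)
    ax.set_yticks(range(n), dm.ids, fontsize=7)
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(n - 0.5, -0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
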