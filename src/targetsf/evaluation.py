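"""Early-enrichment evaluation of ranked virtual screens.

The central quantities are the enrichment factor in the top 1% of the
ranked library (EF1%) and its normalized form (NEF1%):

    EF_f  = (actives retrieved in the top floor(f·N) molecules / A) / f
    NEF_f = EF_f / maxEF_f,   maxEF_f = min(floor(f·N), A) / A / f

i.e. the recall-at-top-fraction divided by the fraction, normalized by
the best value any ranking could achieve on the same test set. NEF lies
in [0, 1] and is comparable across test sets of different sizes; the
expected NEF of a random ranking is 1 / maxEF.

Also provided: precision-recall curves, the median-run selection rule
used to draw one representative of repeated training runs, Tanimoto
dissimilarity filtering of a test set against the training set, hit
clustering at a similarity cutoff, and Shapiro-Wilk/Welch group
comparisons of NEF distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .features import similarity_fingerprint

logger = logging.getLogger("targetsf.evaluation")

__all__ = [
    "RankedScreen",
    "EnrichmentReport",
    "ClusterAssignment",
    "rank",
    "ef_fraction",
    "max_ef_fraction",
    "nef_fraction",
    "random_nef",
    "enrichment_report",
    "pr_curve",
    "pr_auc",
    "select_median_run",
    "dissimilar_filter",
    "nearest_training_similarity",
    "cluster_by_similarity",
    "compare_nef_groups",
    "plot_pr_curves",
]

DEFAULT_TOP_FRACTION = 0.01
SIMILARITY_CUTOFF = 0.70


@dataclass
class RankedScreen:
    """A descending-score ranking of screened molecules."""

    compound_ids: list[str]
    scores: np.ndarray
    is_active: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.is_active = np.asarray(self.is_active, dtype=bool)
        if not (len(self.compound_ids) == len(self.scores)
                == len(self.is_active)):
            raise ValueError("ranking fields have unequal lengths")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_actives(self) -> int:
        return int(self.is_active.sum())


@dataclass
class EnrichmentReport:
    """EF/NEF at one top fraction plus the PR curve of the screen."""

    n_top: int
    ef: float
    nef: float
    max_ef: float
    random_nef: float
    pr_points: list[tuple[float, float]] = field(default_factory=list)
    pr_area: float = float("nan")
    clamped: bool = False  # top bin clamped to 1 because f·N < 1


def rank(compound_ids, scores, labels, tie_break: str = "id",
         tie_seed: int | None = None) -> RankedScreen:
    """Order molecules by descending score.

    Exact score ties are broken by ascending compound id (deterministic
    default); ``tie_break='shuffle'`` instead shuffles tied runs with
    ``tie_seed`` for randomization studies.
    """
    ids = [str(c) for c in compound_ids]
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(ids) == 0:
        raise ValueError("empty screen")
    if not (len(ids) == len(scores) == len(labels)):
        raise ValueError("inputs have unequal lengths")
    if tie_break == "id":
        order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    elif tie_break == "shuffle":
        rng = np.random.default_rng(tie_seed)
        jitter = rng.permutation(len(ids))
        order = sorted(range(len(ids)), key=lambda i: (-scores[i], jitter[i]))
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return RankedScreen(
        compound_ids=[ids[i] for i in order],
        scores=scores[order],
        is_active=labels[order])


def _top_bin(n: int, f: float) -> tuple[int, bool]:
    n_top = math.floor(f * n)
    if n_top < 1:
        return 1, True
    return n_top, False


def ef_fraction(screen: RankedScreen, f: float = DEFAULT_TOP_FRACTION,
                variant: str = "recall") -> float:
    """Enrichment factor in the top ``f`` fraction of the ranking.

    ``variant='recall'`` (default): EF = (hits in top n_top / A) / f with
    n_top = floor(f·N), the convention whose maximum is min(n_top, A)/A/f.
    ``variant='precision'``: EF = (hits/n_top) / (A/N), the hit-rate-ratio
    form, kept available for comparison with tools that use it.
    """
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    if screen.n_actives < 1:
        raise ValueError("enrichment undefined without actives")
    n_top, clamped = _top_bin(screen.n, f)
    if clamped:
        logger.info("top bin clamped to 1 molecule (f·N < 1)")
    hits = int(screen.is_active[:n_top].sum())
    if variant == "recall":
        return (hits / screen.n_actives) / f
    if variant == "precision":
        return (hits / n_top) / (screen.n_actives / screen.n)
    raise ValueError(f"unknown EF variant {variant!r}")


def max_ef_fraction(n: int, n_actives: int,
                    f: float = DEFAULT_TOP_FRACTION) -> float:
    """Best EF (recall form) any ranking can reach on this test set."""
    if n_actives < 1:
        raise ValueError("need at least one active")
    n_top, _ = _top_bin(n, f)
    return min(n_top, n_actives) / n_actives / f


def nef_fraction(screen: RankedScreen,
                 f: float = DEFAULT_TOP_FRACTION) -> float:
    """Normalized enrichment factor, in [0, 1]."""
    return ef_fraction(screen, f) / max_ef_fraction(screen.n,
                                                    screen.n_actives, f)


def random_nef(n: int, n_actives: int,
               f: float = DEFAULT_TOP_FRACTION) -> float:
    """Expected NEF of a random ranking: EF=1 normalized by the maximum."""
    return 1.0 / max_ef_fraction(n, n_actives, f)


def pr_curve(screen: RankedScreen) -> list[tuple[float, float]]:
    """(recall, precision) points at every score threshold."""
    from sklearn.metrics import precision_recall_curve

    precision, recall, _ = precision_recall_curve(
        screen.is_active.astype(int), screen.scores)
    return list(zip(recall.tolist(), precision.tolist()))


def pr_auc(screen: RankedScreen) -> float:
    """Area under the PR curve by step integration (average precision)."""
    from sklearn.metrics import average_precision_score

    return float(average_precision_score(screen.is_active.astype(int),
                                         screen.scores))


def enrichment_report(screen: RankedScreen,
                      f: float = DEFAULT_TOP_FRACTION) -> EnrichmentReport:
    """EF/NEF/PR summary of one ranked screen."""
    n_top, clamped = _top_bin(screen.n, f)
    ef = ef_fraction(screen, f)
    max_ef = max_ef_fraction(screen.n, screen.n_actives, f)
    return EnrichmentReport(
        n_top=n_top, ef=ef, nef=ef / max_ef, max_ef=max_ef,
        random_nef=1.0 / max_ef, pr_points=pr_curve(screen),
        pr_area=pr_auc(screen), clamped=clamped)


def select_median_run(runs, nef_values=None, seed: int | None = None):
    """Pick the run whose NEF is (closest to) the median across runs.

    ``runs`` may be any sequence; ``nef_values`` defaults to each run's
    ``nef`` attribute. When several runs are equally close to the
    median, one is chosen at random (seeded, reproducible).
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs")
    nef = np.asarray([r.nef for r in runs] if nef_values is None
                     else nef_values, dtype=float)
    med = float(np.median(nef))
    dist = np.abs(nef - med)
    closest = np.flatnonzero(dist == dist.min())
    if len(closest) == 1:
        return runs[int(closest[0])]
    rng = np.random.default_rng(seed)
    return runs[int(rng.choice(closest))]


# ---------------------------------------------------------------------------
# Similarity-based test-set analyses (RDKit Morgan 2048 bits, radius 2)


def _fps(smiles_by_id: dict[str, str]):
    out = {}
    for cid, smi in smiles_by_id.items():
        fp = similarity_fingerprint(smi)
        if fp is None:
            logger.warning("unparsable SMILES for %s; excluded from "
                           "similarity analysis", cid)
            continue
        out[cid] = fp
    return out


def dissimilar_filter(test_smiles: dict[str, str],
                      train_smiles: dict[str, str],
                      cutoff: float = SIMILARITY_CUTOFF) -> list[str]:
    """Ids of test molecules dissimilar to every training molecule.

    A test molecule survives iff its maximum Tanimoto similarity
    (Morgan, 2048 bits, radius 2) to any training molecule is strictly
    below ``cutoff``. Decoys are subject to the same rule as true test
    molecules.
    """
    from rdkit.DataStructs import BulkTanimotoSimilarity

    train_fps = list(_fps(train_smiles).values())
    kept = []
    for cid, fp in _fps(test_smiles).items():
        if not train_fps:
            kept.append(cid)
            continue
        if max(BulkTanimotoSimilarity(fp, train_fps)) < cutoff:
            kept.append(cid)
    return kept


def nearest_training_similarity(test_smiles: str,
                                training: list[tuple[str, str, str]]
                                ) -> tuple[float, str, str]:
    """Closest training molecule to one test molecule.

    ``training`` holds (id, smiles, label) triples. Returns (similarity,
    training id, training label); ties broken by ascending id.
    """
    from rdkit.DataStructs import TanimotoSimilarity

    if not training:
        raise ValueError("empty training set")
    fp = similarity_fingerprint(test_smiles)
    if fp is None:
        raise ValueError(f"unparsable test SMILES {test_smiles!r}")
    best = None
    for cid, smi, label in sorted(training, key=lambda t: t[0]):
        tfp = similarity_fingerprint(smi)
        if tfp is None:
            continue
        sim = TanimotoSimilarity(fp, tfp)
        if best is None or sim > best[0]:
            best = (float(sim), cid, label)
    if best is None:
        raise ValueError("no parsable training molecules")
    return best


@dataclass
class ClusterAssignment:
    """Single-linkage clusters at a similarity cutoff."""

    assignment: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, k in self.assignment.items():
            out.setdefault(k, []).append(cid)
        return {k: sorted(v) for k, v in out.items()}


def cluster_by_similarity(smiles_by_id: dict[str, str],
                          cutoff: float = SIMILARITY_CUTOFF
                          ) -> ClusterAssignment:
    """Connected components of the similarity-≥-cutoff graph.

    Transitive closure: a chain a~b~c lands in one cluster even if
    sim(a, c) < cutoff. Cluster indices are assigned in order of the
    sorted smallest member id, so the result is input-order invariant.
    """
    from rdkit.DataStructs import BulkTanimotoSimilarity

    if not smiles_by_id:
        raise ValueError("no molecules to cluster")
    ids = sorted(smiles_by_id)
    fps = _fps({cid: smiles_by_id[cid] for cid in ids})
    ids = [cid for cid in ids if cid in fps]
    parent = list(range(len(ids)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    fplist = [fps[cid] for cid in ids]
    for i in range(len(ids)):
        sims = BulkTanimotoSimilarity(fplist[i], fplist[i + 1:])
        for off, sim in enumerate(sims):
            if sim >= cutoff:
                ri, rj = find(i), find(i + 1 + off)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = sorted({find(i) for i in range(len(ids))})
    root_index = {r: k for k, r in enumerate(roots)}
    return ClusterAssignment(
        {ids[i]: root_index[find(i)] for i in range(len(ids))})


# ---------------------------------------------------------------------------
# Group statistics


def compare_nef_groups(group_a, group_b) -> dict:
    """Shapiro-Wilk normality per group plus Welch's two-sided t-test."""
    from scipy import stats

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    out = {"median_a": float(np.median(a)), "median_b": float(np.median(b))}
    for key, g in (("shapiro_p_a", a), ("shapiro_p_b", b)):
        if np.ptp(g) == 0:
            out[key] = None  # constant group: normality undefined
            out[key.replace("_p_", "_flag_")] = "constant"
        else:
            out[key] = float(stats.shapiro(g).pvalue)
    welch = stats.ttest_ind(a, b, equal_var=False)
    out["welch_t"] = float(welch.statistic)
    out["welch_p"] = float(welch.pvalue)
    return out


# ---------------------------------------------------------------------------
# Plotting (basic PR panels)


def plot_pr_curves(curves: dict[str, list[tuple[float, float]]], path=None,
                   title: str = "Precision-recall"):
    """Plot labeled PR curves; saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, points in curves.items():
        pts = sorted(points)
        ax.step([r for r, _ in pts], [p for _, p in pts], where="post",
                label=label)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
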