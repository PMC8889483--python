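"""Visual-scanning transition graphs over the 16 AOIs and their comparison.

Each video becomes an undirected weighted graph on the 16 AOI nodes: a gaze
shift between two different AOIs on consecutive frames adds 1 to the weight
of the undirected edge between them (dwelling in one AOI contributes
nothing — occupancy is the fixation analysis's concern).  The graph is
stored as a symmetric 16x16 adjacency matrix with zero diagonal.  Each
matrix is normalized by the video's total number of transitions, counting
each undirected transition once, so the fractions over unique unordered
pairs sum to 1 and each symmetric cell carries the full pair fraction.

The cohort comparison tests, for every unique pair whose pooled mean
fraction is nonzero, whether the mean per-video transition fraction differs
between groups (two-sided permutation test, Bonferroni over the number of
tested pairs — a data-dependent count, at most 120).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoi import AOI_LABELS, N_AOI
from .ingest import GazeTrack
from .permutation import PermutationResult, permutation_test_columns

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "cohort_mean_matrix",
    "compare_scanning",
    "ScanningComparison",
    "ScanningResults",
    "to_graph",
]

# Flat indices of the unique unordered pairs (i < j) of a 16x16 matrix.
_IU = np.triu_indices(N_AOI, k=1)


@dataclass
class TransitionMatrix:
    """One video's undirected AOI-transition adjacency matrix.

    ``counts`` is symmetric with zero diagonal; ``total_transitions`` is the
    number of gaze shifts (sum of counts over unique pairs).  ``fractions``
    divides by the total, so unique-pair fractions sum to 1; it is undefined
    (zero matrix) when the video has no transitions.
    """

    video_id: str
    diagnosis: str
    counts: np.ndarray
    total_transitions: int

    @property
    def fractions(self) -> np.ndarray:
        if self.total_transitions == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total_transitions


def transition_matrix(track: GazeTrack) -> TransitionMatrix:
    """Count undirected AOI transitions along a track's frame sequence.

    For every consecutive frame pair whose AOIs differ, both symmetric cells
    (i, j) and (j, i) are incremented; identical consecutive AOIs contribute
    nothing.  A constant (or single-frame) track yields the zero matrix.
    """
    seq = np.asarray(track.aoi)
    counts = np.zeros((N_AOI, N_AOI), dtype=np.int64)
    if len(seq) >= 2:
        src, dst = seq[:-1], seq[1:]
        moved = src != dst
        np.add.at(counts, (src[moved], dst[moved]), 1)
        np.add.at(counts, (dst[moved], src[moved]), 1)
    total = int(counts[_IU].sum())
    return TransitionMatrix(track.video_id, track.diagnosis, counts, total)


def cohort_mean_matrix(matrices) -> np.ndarray:
    """Elementwise mean of per-video fraction matrices (symmetric 16x16)."""
    fracs = [m.fractions for m in matrices]
    if not fracs:
        raise ValueError("need at least one transition matrix")
    return np.mean(fracs, axis=0)


def to_graph(matrix: np.ndarray):
    """Export a (mean) transition matrix as a weighted networkx graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(AOI_LABELS)
    for i, j in zip(*np.nonzero(np.triu(matrix, k=1))):
        g.add_edge(AOI_LABELS[i], AOI_LABELS[j], weight=float(matrix[i, j]))
    return g


class ScanningComparison:
    """Cohort comparison of per-video normalized transition matrices.

    Videos with zero transitions carry no fraction information and are
    excluded (logged) before averaging and testing.
    """

    def __init__(self, matrices: list[TransitionMatrix], labels):
        if len(matrices) != len(labels):
            raise ValueError("matrices and labels must have equal length")
        keep = [i for i, m in enumerate(matrices) if m.total_transitions > 0]
        dropped = len(matrices) - len(keep)
        if dropped:
            logger.warning("%d video(s) with zero transitions excluded", dropped)
        self.matrices = [matrices[i] for i in keep]
        self.labels = np.asarray([labels[i] for i in keep], dtype=int)
        self.n_excluded = dropped
        if not (self.labels == 1).any() or not (self.labels == 0).any():
            raise ValueError("both cohorts must contain at least one video "
                             "with transitions")

    @classmethod
    def from_tracks(cls, tracks: list[GazeTrack]) -> "ScanningComparison":
        mats = [transition_matrix(t) for t in tracks]
        return cls(mats, [t.label for t in tracks])

    def fit(self, n_perm: int = 100_000, alpha: float = 0.05,
            seed: int | None = None) -> "ScanningResults":
        """Permutation-test every unique pair with nonzero pooled mean.

        The tested set (hence the Bonferroni divisor m) is decided once from
        the pooled mean over both cohorts, so m is a single number.
        """
        from .fixation import bonferroni_threshold

        values = np.stack([m.fractions[_IU] for m in self.matrices])  # (n, 120)
        pooled_mean = values.mean(axis=0)
        tested = np.flatnonzero(pooled_mean > 0)
        m = len(tested)
        if m == 0:
            raise ValueError("no nonzero transition cells to test")
        threshold = bonferroni_threshold(alpha, m)
        rng = np.random.default_rng(seed)
        d, p, n_used, exact = permutation_test_columns(values[:, tested],
                                                       self.labels, n_perm, rng)
        pair_names = [f"{AOI_LABELS[_IU[0][t]]}-{AOI_LABELS[_IU[1][t]]}"
                      for t in tested]
        results = [
            PermutationResult(pair_names[q], float(d[q]), float(p[q]),
                              n_used, bool(p[q] < threshold), exact)
            for q in range(m)
        ]
        mean_asd = cohort_mean_matrix(
            [mm for mm, lb in zip(self.matrices, self.labels) if lb == 1])
        mean_nt = cohort_mean_matrix(
            [mm for mm, lb in zip(self.matrices, self.labels) if lb == 0])
        return ScanningResults(results, mean_asd, mean_nt, alpha, threshold,
                               m, n_perm, self.n_excluded)


@dataclass
class ScanningResults:
    """Per-pair permutation results plus cohort mean adjacency matrices."""

    results: list[PermutationResult]
    mean_asd: np.ndarray
    mean_nt: np.ndarray
    alpha: float
    threshold: float
    n_tested: int
    n_perm: int
    n_excluded: int = 0

    @property
    def significant_pairs(self) -> list[str]:
        return [r.cell for r in self.results if r.significant]

    def pair_fraction(self, aoi_a: str, aoi_b: str, cohort: str = "ASD") -> float:
        """Mean fraction of a cohort's transitions on one undirected pair."""
        from .aoi import label_to_code
        i, j = label_to_code(aoi_a), label_to_code(aoi_b)
        mat = self.mean_asd if cohort.upper() == "ASD" else self.mean_nt
        return float(mat[i, j])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair": [r.cell for r in self.results],
            "observed_diff": [r.observed_diff for r in self.results],
            "p_value": [r.p_value for r in self.results],
            "significant": [r.significant for r in self.results],
        })

    def mean_matrix_frame(self, cohort: str = "ASD") -> pd.DataFrame:
        mat = self.mean_asd if cohort.upper() == "ASD" else self.mean_nt
        return pd.DataFrame(mat, index=list(AOI_LABELS),
                            columns=list(AOI_LABELS))

    def summary(self, top: int = 10) -> str:
        from .fixation import _format_p
        lines = [
            "Visual-scanning cohort comparison (two-sided permutation tests)",
            f"  tested pairs: {self.n_tested}; permutations: {self.n_perm}; "
            f"alpha: {self.alpha}; Bonferroni threshold: {self.threshold:.4f}",
            f"  excluded zero-transition videos: {self.n_excluded}",
            f"{'pair':>7} {'ASD mean':>9} {'NT mean':>9} "
            f"{'diff':>9} {'p':>10}  sig",
        ]
        ordered = sorted(self.results, key=lambda r: r.p_value)[:top]
        for r in ordered:
            a, b = r.cell.split("-")
            lines.append(
                f"{r.cell:>7} {self.pair_fraction(a, b, 'ASD'):>9.4f} "
                f"{self.pair_fraction(a, b, 'NT'):>9.4f} "
                f"{r.observed_diff:>+9.4f} "
                f"{_format_p(r.p_value, r.n_permutations):>10}"
                f"  {'*' if r.significant else ''}"
            )
        return "\n".join(lines)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.frame().to_csv(out_dir / "scanning_tests.csv", index=False)
        self.mean_matrix_frame("ASD").to_csv(out_dir / "scanning_mean_asd.csv")
        self.mean_matrix_frame("NT").to_csv(out_dir / "scanning_mean_nt.csv")

    def plot_heatmaps(self, out_path=None):
        """16x16 heat maps of the two cohort mean adjacency matrices."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(11, 5))
        vmax = max(self.mean_asd.max(), self.mean_nt.max())
        for ax, mat, title in ((axes[0], self.mean_asd, "ASD"),
                               (axes[1], self.mean_nt, "NT")):
            im = ax.imshow(mat, cmap="viridis", vmin=0, vmax=vmax)
            ax.set_xticks(range(16), list(AOI_LABELS), rotation=90, fontsize=6)
            ax.set_yticks(range(16), list(AOI_LABELS), fontsize=6)
            ax.set_title(f"{title} mean transition fractions")
            fig.colorbar(im, ax=ax, fraction=0.046)
        fig.tight_layout()
        if out_path is not None:
            fig.savefig(out_path, dpi=120)
            plt.close(fig)
        return fig


def compare_scanning(matrices, labels, n_perm: int = 100_000,
                     alpha: float = 0.05,
                     seed: int | None = None) -> ScanningResults:
    """Functional wrapper: build a :class:`ScanningComparison` and fit it."""
    return ScanningComparison(matrices, labels).fit(n_perm=n_perm,
                                                    alpha=alpha, seed=seed)
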