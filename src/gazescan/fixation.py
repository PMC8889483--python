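"""Gaze-fixation profiles over the 16 AOIs and their cohort comparison.

A video's fixation profile is the fraction of its valid (retained) frames
spent in each AOI; the cohort analysis asks, AOI by AOI, whether the mean
per-video fixation fraction differs between the ASD and NT groups, using a
two-sided permutation test with Bonferroni correction over the 16 AOIs.

The unit of analysis is the video, matching the per-video profiles of the
emulated study; because several videos can come from one child they are not
independent, and a child-level mode (mean profile per child) is provided via
``unit="child"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoi import AOI_LABELS, N_AOI
from .ingest import GazeTrack
from .permutation import PermutationResult, permutation_test_columns

__all__ = [
    "FixationProfile",
    "fixation_profile",
    "bonferroni_threshold",
    "compare_fixation",
    "FixationComparison",
    "FixationResults",
]


@dataclass(frozen=True)
class FixationProfile:
    """Per-video AOI occupancy: fraction of valid frames in each of 16 AOIs."""

    video_id: str
    diagnosis: str
    fractions: np.ndarray  # (16,), sums to 1

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=list(AOI_LABELS),
                         name=self.video_id)


def fixation_profile(track: GazeTrack) -> FixationProfile:
    """Fraction of a track's frames fixated in each AOI.

    Raises ``ValueError("no valid frames")`` on an empty sequence.
    """
    if len(track) == 0:
        raise ValueError("no valid frames")
    counts = np.bincount(track.aoi, minlength=N_AOI).astype(float)
    return FixationProfile(track.video_id, track.diagnosis,
                           counts / counts.sum())


def bonferroni_threshold(alpha: float = 0.05, m: int = 16) -> float:
    """Per-test significance threshold alpha/m for m hypothesis tests.

    With alpha=0.05: m=16 gives 0.003125 (displayed 0.0031) and m=61 gives
    ~0.00082 (displayed 0.0008).  Display rounding is the reporting layer's
    concern; the exact quotient is returned.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


class FixationComparison:
    """Cohort comparison of per-video fixation profiles.

    Parameters
    ----------
    profiles : list of FixationProfile (or build with :meth:`from_tracks`).
    labels : per-profile group indicator, 1 = ASD, 0 = NT.
    child_ids : optional per-profile child identifiers, required for
        ``unit="child"`` aggregation.
    """

    def __init__(self, profiles, labels, child_ids=None):
        if len(profiles) != len(labels):
            raise ValueError("profiles and labels must have equal length")
        self.profiles = list(profiles)
        self.labels = np.asarray(labels, dtype=int)
        self.child_ids = list(child_ids) if child_ids is not None else None
        if not (self.labels == 1).any() or not (self.labels == 0).any():
            raise ValueError("both cohorts must contain at least one video")

    @classmethod
    def from_tracks(cls, tracks: list[GazeTrack]) -> "FixationComparison":
        tracks = [t for t in tracks if len(t) > 0]
        profiles = [fixation_profile(t) for t in tracks]
        labels = [t.label for t in tracks]
        return cls(profiles, labels, child_ids=[t.child_id for t in tracks])

    def _value_matrix(self, unit: str):
        values = np.stack([p.fractions for p in self.profiles])
        if unit == "video":
            return values, self.labels
        if unit != "child":
            raise ValueError(f"unknown unit: {unit!r}")
        if self.child_ids is None:
            raise ValueError("child-level aggregation needs child_ids")
        df = pd.DataFrame(values)
        df["child"] = self.child_ids
        df["label"] = self.labels
        agg = df.groupby("child", sort=True).mean()
        return agg.drop(columns="label").to_numpy(), \
            agg["label"].round().astype(int).to_numpy()

    def fit(self, n_perm: int = 100_000, alpha: float = 0.05,
            seed: int | None = None, unit: str = "video") -> "FixationResults":
        """Run one permutation test per AOI with Bonferroni m=16."""
        values, labels = self._value_matrix(unit)
        rng = np.random.default_rng(seed)
        threshold = bonferroni_threshold(alpha, N_AOI)
        d, p, n_used, exact = permutation_test_columns(values, labels,
                                                       n_perm, rng)
        results = [
            PermutationResult(AOI_LABELS[k], float(d[k]), float(p[k]),
                              n_used, bool(p[k] < threshold), exact)
            for k in range(N_AOI)
        ]
        mean_asd = values[labels == 1].mean(axis=0)
        mean_nt = values[labels == 0].mean(axis=0)
        return FixationResults(results, mean_asd, mean_nt, alpha, threshold,
                               n_perm, unit)


@dataclass
class FixationResults:
    """Per-AOI permutation-test results plus cohort mean profiles."""

    results: list[PermutationResult]
    mean_asd: np.ndarray
    mean_nt: np.ndarray
    alpha: float
    threshold: float
    n_perm: int
    unit: str = "video"

    @property
    def significant_aois(self) -> list[str]:
        return [r.cell for r in self.results if r.significant]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "aoi": [r.cell for r in self.results],
            "observed_diff": [r.observed_diff for r in self.results],
            "p_value": [r.p_value for r in self.results],
            "significant": [r.significant for r in self.results],
        })

    def mean_profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"aoi": list(AOI_LABELS),
                             "mean_asd": self.mean_asd,
                             "mean_nt": self.mean_nt})

    def summary(self) -> str:
        lines = [
            "Gaze-fixation cohort comparison (two-sided permutation tests)",
            f"  unit: {self.unit}; permutations: {self.n_perm}; "
            f"alpha: {self.alpha}; Bonferroni threshold: {self.threshold:.4f}",
            f"{'AOI':>4} {'ASD mean':>9} {'NT mean':>9} "
            f"{'diff':>9} {'p':>10}  sig",
        ]
        for k, r in enumerate(self.results):
            lines.append(
                f"{r.cell:>4} {self.mean_asd[k]:>9.4f} {self.mean_nt[k]:>9.4f} "
                f"{r.observed_diff:>+9.4f} {_format_p(r.p_value, r.n_permutations):>10}"
                f"  {'*' if r.significant else ''}"
            )
        return "\n".join(lines)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.frame().to_csv(out_dir / "fixation_tests.csv", index=False)
        self.mean_profiles_frame().to_csv(out_dir / "fixation_mean_profiles.csv",
                                          index=False)

    def plot_heatmaps(self, out_path=None):
        """4x4 heat maps of the two cohort mean profiles (one per cohort)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(8, 4))
        for ax, vec, title in ((axes[0], self.mean_asd, "ASD"),
                               (axes[1], self.mean_nt, "NT")):
            im = ax.imshow(vec.reshape(4, 4), cmap="viridis", vmin=0)
            ax.set_xticks(range(4), list("ABCD"))
            ax.set_yticks(range(4), list("ABCD"))
            ax.set_title(f"{title} mean fixation fraction")
            fig.colorbar(im, ax=ax, fraction=0.046)
        fig.tight_layout()
        if out_path is not None:
            fig.savefig(out_path, dpi=120)
            plt.close(fig)
        return fig


def _format_p(p: float, n_perm: int) -> str:
    """Display a Monte-Carlo p-value, bounding values below the resolution."""
    if p < 0.001 or p <= 1.0 / (n_perm + 1):
        return "<.001" if p < 0.001 else f"<{1.5 / (n_perm + 1):.4f}"
    return f"{p:.4f}"


def compare_fixation(profiles, labels, n_perm: int = 100_000,
                     alpha: float = 0.05, seed: int | None = None,
                     unit: str = "video", child_ids=None) -> FixationResults:
    """Functional wrapper: build a :class:`FixationComparison` and fit it."""
    return FixationComparison(profiles, labels, child_ids).fit(
        n_perm=n_perm, alpha=alpha, seed=seed, unit=unit)
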