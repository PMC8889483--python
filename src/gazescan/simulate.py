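"""Synthetic gaze-annotation cohorts with planted group structure.

The study design being emulated: children play a 90-second charades-style
game on a phone while the front camera records them; per-frame gaze
estimation yields one (x, y) coordinate pair per frame plus a face count and
an estimation confidence.  No such data set is publicly deposited, so this
module generates cohorts with the statistical structure the downstream
analyses assume:

* each cohort (ASD / NT) has its own 16-state AOI transition kernel, so both
  occupancy (fixation) and transition (scanning) differences can be planted;
* each child contributes several videos (overdispersed count, mean 4.7 like
  the emulated study) and carries a random per-child perturbation of the
  cohort kernel, which makes child-grouped train/test splits meaningful;
* a configurable fraction of frames is emitted as "dropout": plausible
  coordinates but failing exactly one quality criterion (low confidence, or
  a face count of 0 or 3), so both ingest filters are exercised.

The AOI state sequence of a video is a first-order Markov chain; the emitted
coordinate is drawn inside the current AOI's cell (uniform by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .aoi import AOI_CODES, CELL_SIZE, N_AOI, cell_bounds

__all__ = [
    "CohortSpec",
    "make_default_kernels",
    "simulate_cohort",
    "write_cohort",
    "kernel_stationary",
    "kernel_edge_fractions",
    "ANNOTATION_COLUMNS",
    "METADATA_COLUMNS",
]

ANNOTATION_COLUMNS = (
    "video_id",
    "child_id",
    "frame_index",
    "n_faces",
    "confidence",
    "gaze_x",
    "gaze_y",
)
METADATA_COLUMNS = ("child_id", "diagnosis", "age", "sex")

# Target stationary occupancy of the neurotypical kernel.  Mass concentrates
# on the four central AOIs (closest to the camera), with BB and BC the two
# largest; the full-effect ASD kernel swaps the BC and CB masses, so its two
# largest are BB and CB and the planted differences sit at AOI BC (fixation)
# and edge BB-BC (scanning).
_CENTRAL_MASS = {"BB": 0.30, "BC": 0.25, "CB": 0.12, "CC": 0.10}
#: Probability of dwelling in the current AOI at each frame step.
_DWELL = 0.55


def _nt_stationary() -> np.ndarray:
    pi = np.empty(N_AOI)
    rest = 1.0 - sum(_CENTRAL_MASS.values())
    pi[:] = rest / (N_AOI - len(_CENTRAL_MASS))
    for lab, mass in _CENTRAL_MASS.items():
        pi[AOI_CODES[lab]] = mass
    return pi


def make_default_kernels(effect_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Build the cohort AOI transition kernels for a given effect size.

    Both kernels have the dwell-plus-jump form ``K = a*I + (1-a)*1 pi^T``
    with dwell probability ``a`` fixed, so the stationary occupancy is
    exactly ``pi`` and every off-diagonal transition flow is proportional to
    ``pi_i * pi_j``.  The NT kernel uses a fixed occupancy with its two
    largest masses on BB and BC; at ``effect_size=1`` the ASD occupancy
    swaps the BC and CB masses (largest two: BB and CB), and intermediate
    effect sizes interpolate linearly.  ``effect_size=0`` gives identical
    kernels.

    Parameters
    ----------
    effect_size : float in [0, 1]
        0 = no cohort difference; 1 = full planted contrast.

    Returns
    -------
    (asd_kernel, nt_kernel) : two row-stochastic (16, 16) arrays.
    """
    effect_size = float(effect_size)
    if not 0.0 <= effect_size <= 1.0:
        raise ValueError(f"effect_size must be in [0, 1], got {effect_size}")
    pi_nt = _nt_stationary()
    pi_asd_full = pi_nt.copy()
    bc, cb = AOI_CODES["BC"], AOI_CODES["CB"]
    pi_asd_full[bc], pi_asd_full[cb] = pi_nt[cb], pi_nt[bc]
    pi_asd = (1.0 - effect_size) * pi_nt + effect_size * pi_asd_full

    def kernel(pi: np.ndarray) -> np.ndarray:
        return _DWELL * np.eye(N_AOI) + (1.0 - _DWELL) * np.tile(pi, (N_AOI, 1))

    return kernel(pi_asd), kernel(pi_nt)


def kernel_stationary(kernel: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Stationary distribution of a row-stochastic kernel (power iteration)."""
    pi = np.full(N_AOI, 1.0 / N_AOI)
    for _ in range(n_iter):
        pi = pi @ kernel
    return pi / pi.sum()


def kernel_edge_fractions(kernel: np.ndarray) -> np.ndarray:
    """Expected undirected transition fractions implied by a kernel.

    The stationary flow on the directed edge i->j is ``pi_i * K[i, j]``; the
    undirected edge (i, j) carries the sum of both directions.  Fractions
    are normalized over off-diagonal (i < j) pairs, returned as a symmetric
    matrix with zero diagonal where cell (i, j) holds the full fraction of
    the unordered pair, matching the convention of
    :mod:`gazescan.scanning`.
    """
    pi = kernel_stationary(kernel)
    flow = pi[:, None] * kernel
    und = flow + flow.T
    np.fill_diagonal(und, 0.0)
    total = und.sum() / 2.0
    return und / total


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-cohort gaze study.

    Defaults mirror the emulated study design: ~90 s of gameplay at 25 fps
    (2250 frames per video), a mean of 4.7 videos per child with large
    overdispersion (SD 7.3), and ~43% of raw frames failing quality control.
    """

    n_children_asd: int = 10
    n_children_nt: int = 10
    videos_per_child_mean: float = 4.7
    videos_per_child_sd: float = 7.3
    frames_per_video: int = 2250
    effect_size: float = 1.0
    asd_kernel: np.ndarray | None = None
    nt_kernel: np.ndarray | None = None
    dropout_rate: float = 0.43
    jitter_sd: float = 0.15
    coord_mode: str = "uniform"  # "uniform" | "gaussian"
    child_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_children_asd < 0 or self.n_children_nt < 0:
            raise ValueError("child counts must be >= 0")
        if self.frames_per_video < 1:
            raise ValueError("frames_per_video must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.coord_mode not in ("uniform", "gaussian"):
            raise ValueError(f"unknown coord_mode: {self.coord_mode!r}")
        if self.videos_per_child_mean < 1.0:
            raise ValueError("videos_per_child_mean must be >= 1")
        for name in ("asd_kernel", "nt_kernel"):
            k = getattr(self, name)
            if k is None:
                continue
            k = np.asarray(k, dtype=float)
            if k.shape != (N_AOI, N_AOI) or np.any(k < 0):
                raise ValueError(f"{name} must be a non-negative 16x16 matrix")
            if not np.allclose(k.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1 within 1e-9")
            object.__setattr__(self, name, k)

    def kernels(self) -> tuple[np.ndarray, np.ndarray]:
        """The (asd, nt) kernels: explicit ones if given, else the defaults."""
        if self.asd_kernel is not None and self.nt_kernel is not None:
            return self.asd_kernel, self.nt_kernel
        return make_default_kernels(self.effect_size)


def _perturb_kernel(kernel: np.ndarray, sd: float, rng) -> np.ndarray:
    """Per-child kernel: Gaussian noise on row logits, renormalized."""
    if sd == 0.0:
        return kernel
    logits = np.log(np.maximum(kernel, 1e-12))
    logits = logits + rng.normal(0.0, sd, size=kernel.shape)
    out = np.exp(logits - logits.max(axis=1, keepdims=True))
    return out / out.sum(axis=1, keepdims=True)


def _sample_chain(kernel: np.ndarray, n: int, rng) -> np.ndarray:
    """Sample an n-step Markov chain, started from the kernel's stationary."""
    cum = np.cumsum(kernel, axis=1)
    pi_cum = np.cumsum(kernel_stationary(kernel))
    states = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    states[0] = np.searchsorted(pi_cum, u[0])
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return np.minimum(states, N_AOI - 1)


def _coords_for_states(states: np.ndarray, spec: CohortSpec, rng):
    """Draw (x, y) inside each state's cell: x in [x_min, x_max), y in (y_min, y_max]."""
    n = len(states)
    bounds = np.array([cell_bounds(c) for c in range(N_AOI)])
    x_min, y_max = bounds[states, 0], bounds[states, 3]
    if spec.coord_mode == "uniform":
        x = x_min + rng.random(n) * CELL_SIZE
        y = y_max - rng.random(n) * CELL_SIZE
    else:
        # Truncated Gaussian around the cell center; clipped strictly inside
        # so the emitted coordinate always maps back to the emitting cell.
        eps = 1e-9
        cx = x_min + CELL_SIZE / 2.0
        cy = y_max - CELL_SIZE / 2.0
        x = np.clip(cx + rng.normal(0.0, spec.jitter_sd, n),
                    x_min, x_min + CELL_SIZE - eps)
        y = np.clip(cy + rng.normal(0.0, spec.jitter_sd, n),
                    y_max - CELL_SIZE + eps, y_max)
    return x, y


def _videos_per_child(spec: CohortSpec, rng) -> int:
    """Overdispersed video count, >= 1 (negative binomial when SD^2 > mean)."""
    mean, var = spec.videos_per_child_mean, spec.videos_per_child_sd**2
    if var == 0:
        k = round(mean)
    elif var <= mean:
        k = rng.poisson(mean)
    else:
        r = mean**2 / (var - mean)
        p = mean / var
        k = rng.negative_binomial(r, p)
    return max(1, int(k))


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-cohort study; returns (annotations, metadata) tables.

    The annotation table has one row per frame with columns
    ``video_id, child_id, frame_index, n_faces, confidence, gaze_x, gaze_y``;
    the metadata table has one row per child with columns
    ``child_id, diagnosis, age, sex``.  Fixed seed gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    asd_kernel, nt_kernel = spec.kernels()

    meta_rows = []
    ann_parts = []
    cohorts = [("ASD", spec.n_children_asd, asd_kernel, 53 / 68),
               ("NT", spec.n_children_nt, nt_kernel, 18 / 27)]
    for diagnosis, n_children, kernel, p_male in cohorts:
        for i in range(n_children):
            child_id = f"{diagnosis.lower()}{i + 1:03d}"
            meta_rows.append({
                "child_id": child_id,
                "diagnosis": diagnosis,
                "age": int(rng.integers(2, 16)),
                "sex": "M" if rng.random() < p_male else "F",
            })
            child_kernel = _perturb_kernel(kernel, spec.child_effect_sd, rng)
            for v in range(_videos_per_child(spec, rng)):
                video_id = f"{child_id}_v{v + 1:02d}"
                n = spec.frames_per_video
                states = _sample_chain(child_kernel, n, rng)
                x, y = _coords_for_states(states, spec, rng)
                n_faces = np.ones(n, dtype=np.int64)
                confidence = 0.75 + 0.25 * rng.random(n)
                drop = rng.random(n) < spec.dropout_rate
                # Each dropout frame fails exactly one filter, chosen at
                # random, so both quality criteria are exercised.
                conf_fail = drop & (rng.random(n) < 0.5)
                face_fail = drop & ~conf_fail
                confidence[conf_fail] = 0.75 * rng.random(conf_fail.sum())
                n_faces[face_fail] = rng.choice([0, 3], size=face_fail.sum())
                ann_parts.append(pd.DataFrame({
                    "video_id": video_id,
                    "child_id": child_id,
                    "frame_index": np.arange(n, dtype=np.int64),
                    "n_faces": n_faces,
                    "confidence": confidence,
                    "gaze_x": x,
                    "gaze_y": y,
                }))

    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    if ann_parts:
        annotations = pd.concat(ann_parts, ignore_index=True)
    else:
        annotations = pd.DataFrame(columns=list(ANNOTATION_COLUMNS))
    return annotations, metadata


def write_cohort(spec: CohortSpec, out_dir) -> tuple[Path, Path]:
    """Simulate and write the canonical CSVs; returns their paths.

    UTF-8, '.' decimal separator, one header line; float columns use
    repr-round-trip formatting, so a fixed seed yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations, metadata = simulate_cohort(spec)
    ann_path = out_dir / "annotations.csv"
    meta_path = out_dir / "metadata.csv"
    annotations.to_csv(ann_path, index=False)
    metadata.to_csv(meta_path, index=False)
    return ann_path, meta_path
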