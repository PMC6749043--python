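"""Spectral preprocessing: region exclusion, adaptive binning, probabilistic
quotient normalization (PQN) and pareto scaling.

The pipeline mirrors standard serum 1H-NMR practice: drop the
water-dominated region (4.33-5.50 ppm), integrate variable-width bins whose
boundaries avoid splitting peaks (mean width ~0.015 ppm), correct per-sample
dilution with PQN, then mean-center and pareto-scale for multivariate
modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

WATER_REGION = (4.33, 5.50)  # ppm, inclusive
DEFAULT_BIN_WIDTH = 0.015  # ppm, target mean width

STAGES = ("binned", "normalized", "scaled")


@dataclass
class Spectrum:
    """A single sample's (ppm, intensity) trace with metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = "sample"
    group: str | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have equal length")
        if np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class FeatureMatrix:
    """Samples x features table with bin-edge metadata and a stage tag."""

    values: pd.DataFrame  # index = sample_id, columns = feature ints
    feature_meta: pd.DataFrame  # columns: left, right, center (ppm)
    sample_meta: pd.DataFrame  # index = sample_id, column: group
    stage: str = "binned"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if len(self.values) != len(self.sample_meta):
            raise ValueError("row count must equal number of samples")
        if len(self.values.columns) != len(self.feature_meta):
            raise ValueError("feature_meta must describe every column")

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        groups: Sequence[str] | pd.Series,
        stage: str = "normalized",
        centers: Sequence[float] | None = None,
    ) -> "FeatureMatrix":
        """Wrap a plain samples x features table (e.g. metabolite integrals)."""
        centers = np.arange(values.shape[1], dtype=float) if centers is None else np.asarray(centers, float)
        meta = pd.DataFrame({"left": centers, "right": centers, "center": centers})
        vals = values.copy()
        vals.columns = range(values.shape[1])
        sm = pd.DataFrame({"group": list(groups)}, index=values.index)
        return cls(vals, meta, sm, stage)

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta["group"]


@dataclass
class NormalizationReport:
    """Per-sample dilution estimates from PQN.

    ``dilution_estimate`` combines the total-integral factor with the median
    quotient and tracks the injected per-sample scale on synthetic data.
    """

    table: pd.DataFrame  # index sample_id: integral_factor, quotient, dilution_estimate
    reference: str


def exclude_region(
    spectrum: Spectrum, low: float = WATER_REGION[0], high: float = WATER_REGION[1]
) -> Spectrum:
    """Drop all points with ppm in [low, high], preserving order."""
    if low >= high:
        raise ValueError("low must be < high")
    keep = (spectrum.ppm < low) | (spectrum.ppm > high)
    if not keep.any():
        raise ValueError("exclusion window covers the entire spectrum")
    return Spectrum(
        ppm=spectrum.ppm[keep],
        intensity=spectrum.intensity[keep],
        sample_id=spectrum.sample_id,
        group=spectrum.group,
    )


def _segments(ppm: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous index ranges of the (possibly gapped) retained grid."""
    dx = np.diff(ppm)
    step = np.median(dx)
    breaks = np.where(dx > 2.5 * step)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [ppm.size - 1]))
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b > a]


def _segment_edges(
    ppm: np.ndarray, mean_int: np.ndarray, a: int, b: int, target_width: float
) -> list[int]:
    """Edge indices for one contiguous segment.

    Uniform seed boundaries at ``target_width`` spacing are each moved to
    the lowest point of the cohort-mean spectrum within +/-40% of the target
    width (ties resolve to the seed, so flat spectra keep uniform bins),
    then bins narrower than 25% of the target are merged into their
    narrower neighbour.
    """
    length = ppm[b] - ppm[a]
    n_bins = max(1, round(length / target_width))
    seed_ppm = np.linspace(ppm[a], ppm[b], n_bins + 1)[1:-1]
    edges = [a]
    for sp in seed_ppm:
        seed_idx = a + int(np.argmin(np.abs(ppm[a : b + 1] - sp)))
        lo = a + int(np.searchsorted(ppm[a : b + 1], sp - 0.4 * target_width))
        hi = a + int(np.searchsorted(ppm[a : b + 1], sp + 0.4 * target_width, "right")) - 1
        window = mean_int[lo : hi + 1]
        m = window.min()
        ties = np.flatnonzero(window <= m + 1e-12 * max(1.0, abs(m)))
        best = lo + int(ties[np.argmin(np.abs(ties + lo - seed_idx))])
        edges.append(best)
    edges.append(b)
    edges = sorted(set(edges))
    # merge undersized bins
    min_width = 0.25 * target_width
    while len(edges) > 2:
        widths = np.diff(ppm[edges])
        i = int(np.argmin(widths))
        if widths[i] >= min_width:
            break
        if i == 0:
            drop = 1
        elif i == len(widths) - 1:
            drop = len(edges) - 2
        else:
            drop = i if widths[i - 1] <= widths[i + 1] else i + 1
        edges.pop(drop)
    return edges


def adaptive_bin(
    spectra: Sequence[Spectrum], target_width: float = DEFAULT_BIN_WIDTH
) -> FeatureMatrix:
    """Adaptively bin a cohort of spectra sharing one (gapped) grid.

    Bin boundaries sit at local minima of the cohort-mean spectrum so that
    peaks are not split; each cell is the trapezoidal integral of that
    sample's intensity over the bin. Bins partition each retained segment,
    so per-sample bin integrals sum to the full trapezoidal integral.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    if target_width <= 0:
        raise ValueError("target_width must be > 0")
    ppm = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != ppm.shape or not np.allclose(s.ppm, ppm):
            raise ValueError("spectra must share a common ppm grid")
    inten = np.vstack([s.intensity for s in spectra])
    mean_int = inten.mean(axis=0)

    lefts: list[float] = []
    rights: list[float] = []
    cells: list[np.ndarray] = []
    for a, b in _segments(ppm):
        edges = _segment_edges(ppm, mean_int, a, b, target_width)
        cum = cumulative_trapezoid(inten[:, a : b + 1], ppm[a : b + 1], axis=1, initial=0.0)
        rel = np.array(edges) - a
        for e0, e1 in zip(rel[:-1], rel[1:]):
            lefts.append(ppm[a + e0])
            rights.append(ppm[a + e1])
            cells.append(cum[:, e1] - cum[:, e0])
    values = pd.DataFrame(
        np.column_stack(cells),
        index=pd.Index([s.sample_id for s in spectra], name="sample_id"),
    )
    meta = pd.DataFrame(
        {"left": lefts, "right": rights,
         "center": (np.array(lefts) + np.array(rights)) / 2}
    )
    sample_meta = pd.DataFrame(
        {"group": [s.group for s in spectra]},
        index=pd.Index([s.sample_id for s in spectra], name="sample_id"),
    )
    return FeatureMatrix(values, meta, sample_meta, stage="binned")


def pqn_normalize(
    matrix: FeatureMatrix,
    reference: str = "all",
    quotient_floor_fraction: float = 0.01,
) -> tuple[FeatureMatrix, NormalizationReport]:
    """Probabilistic quotient normalization.

    Each row is first scaled to the cohort-median total integral, then
    divided by the median of its feature-wise quotients against the
    reference spectrum (the median spectrum over all rows, or over one
    group when ``reference`` names it). Quotients are computed only on
    features whose reference value exceeds ``quotient_floor_fraction`` of
    the reference's median positive value, which keeps noise-dominated and
    negative bins out of the dilution estimate.
    """
    if matrix.stage not in ("binned", "normalized"):
        raise ValueError("PQN expects a binned (or already normalized) matrix")
    X = matrix.values.to_numpy(float)
    totals = X.sum(axis=1)
    zero_rows = np.where(np.abs(totals) <= 0)[0]
    if zero_rows.size:
        bad = matrix.values.index[zero_rows[0]]
        raise ValueError(f"sample {bad!r} has all-zero features")
    if reference == "all":
        ref_rows = np.ones(len(X), bool)
    else:
        ref_rows = (matrix.groups == reference).to_numpy()
        if not ref_rows.any():
            raise ValueError(f"no samples in reference group {reference!r}")
    t_med = float(np.median(totals[ref_rows]))
    integral_factor = totals / t_med
    Xn = X / integral_factor[:, None]
    ref_spectrum = np.median(Xn[ref_rows], axis=0)
    positive = ref_spectrum[ref_spectrum > 0]
    if positive.size == 0:
        raise ValueError("reference spectrum has no positive features")
    floor = quotient_floor_fraction * float(np.median(positive))
    use = ref_spectrum > floor
    quotients = np.median(Xn[:, use] / ref_spectrum[use], axis=1)
    if np.any(quotients <= 0):
        bad = matrix.values.index[int(np.argmin(quotients))]
        raise ValueError(f"non-positive median quotient for sample {bad!r}")
    Xq = Xn / quotients[:, None]
    out = FeatureMatrix(
        pd.DataFrame(Xq, index=matrix.values.index, columns=matrix.values.columns),
        matrix.feature_meta.copy(),
        matrix.sample_meta.copy(),
        stage="normalized",
    )
    report = NormalizationReport(
        table=pd.DataFrame(
            {
                "integral_factor": integral_factor,
                "quotient": quotients,
                "dilution_estimate": integral_factor * quotients,
            },
            index=matrix.values.index,
        ),
        reference=reference,
    )
    return out, report


def scale_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Mean-center then pareto-scale (divide by sqrt of the column sd).

    After scaling a column's variance equals its pre-scaling standard
    deviation, damping the dominance of intense bins without flattening the
    variance structure the way unit-variance scaling would. Constant
    columns are set to zero and flagged with a warning so feature indices
    stay aligned with the bin metadata.
    """
    if matrix.stage != "normalized":
        raise ValueError("scaling expects a normalized matrix")
    X = matrix.values.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to scale")
    centered = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) set to zero after scaling",
            stacklevel=2,
        )
    scaled = np.zeros_like(centered)
    np.divide(centered, np.sqrt(sd, where=~constant, out=np.ones_like(sd)),
              out=scaled, where=~constant)
    meta = matrix.feature_meta.copy()
    meta["pareto_sd"] = sd
    return FeatureMatrix(
        pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns),
        meta,
        matrix.sample_meta.copy(),
        stage="scaled",
    )


def read_spectrum_csv(path: str | Path, sample_id: str | None = None,
                      group: str | None = None) -> Spectrum:
    """Read a per-sample two-column (ppm, intensity) CSV."""
    frame = pd.read_csv(path)
    cols = list(frame.columns[:2])
    order = np.argsort(frame[cols[0]].to_numpy(float))
    return Spectrum(
        ppm=frame[cols[0]].to_numpy(float)[order],
        intensity=frame[cols[1]].to_numpy(float)[order],
        sample_id=sample_id or Path(path).stem,
        group=group,
    )


def write_feature_matrix(matrix: FeatureMatrix, prefix: str | Path) -> dict[str, Path]:
    """Write values + metadata CSVs; stage recorded in the sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": prefix.with_suffix(".csv"),
        "features": prefix.parent / f"{prefix.name}_features.csv",
        "samples": prefix.parent / f"{prefix.name}_samples.csv",
    }
    matrix.values.to_csv(paths["values"], float_format="%.17g")
    meta = matrix.feature_meta.copy()
    meta.insert(0, "stage", matrix.stage)
    meta.to_csv(paths["features"], index_label="feature")
    matrix.sample_meta.to_csv(paths["samples"])
    return paths
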