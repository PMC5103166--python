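"""Spectral pretreatments applied before any chemometric model.

The pipeline order is fixed: multiplicative scatter correction (MSC), then a
gap-segment ("Norris") first derivative, then restriction to the configured
spectral windows.  MSC comes first so the derivative operates on
scatter-corrected spectra; windows are applied last so derivative edge
trimming never eats into window interiors.

MSC regresses each spectrum on a reference (the calibration-set mean) and
removes the fitted offset and slope.  For prediction the reference is always
the stored calibration-set mean — a new sample's correction must not depend
on the batch it arrives in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpectraSet, WavenumberGrid

__all__ = [
    "PreprocessConfig",
    "MSCReference",
    "CorrectionError",
    "DEFAULT_WINDOWS",
    "msc_fit",
    "msc_apply",
    "gap_segment_first_derivative",
    "apply_windows",
    "preprocess",
]

#: Spectral windows (cm^-1) that carry organic-signature information and
#: exclude the water absorption regions; closed intervals.
DEFAULT_WINDOWS = ((4100.0, 4940.0), (5390.0, 6690.0), (6900.0, 7130.0), (7185.0, 9000.0))


class CorrectionError(ValueError):
    """MSC failed on a pathological spectrum (non-positive fitted slope)."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Pretreatment settings.

    derivative ``segment`` (odd point count of the smoothing window) and
    ``gap`` (point offset of the central difference) are in points, the usual
    vendor convention; both default to 5.  ``windows`` are closed [lo, hi]
    cm^-1 intervals, non-overlapping and sorted; ``None`` disables masking.
    """

    msc: bool = True
    derivative: bool = True
    segment: int = 5
    gap: int = 5
    windows: tuple | None = DEFAULT_WINDOWS

    def __post_init__(self):
        if self.derivative:
            if self.segment < 1 or self.segment % 2 == 0:
                raise ValueError("derivative segment must be odd and >= 1")
            if self.gap < 1:
                raise ValueError("derivative gap must be >= 1")
        if self.windows is not None:
            w = tuple((float(lo), float(hi)) for lo, hi in self.windows)
            if any(lo > hi for lo, hi in w):
                raise ValueError("each window needs lo <= hi")
            for (a, b), (c, d) in zip(w, w[1:]):
                if c <= b:
                    raise ValueError("windows must be sorted and non-overlapping")
            object.__setattr__(self, "windows", w)

    def to_dict(self) -> dict:
        return {
            "msc": self.msc,
            "derivative": {
                "enabled": self.derivative,
                "segment": self.segment,
                "gap": self.gap,
            },
            "windows": [list(w) for w in self.windows] if self.windows else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        deriv = d.get("derivative", {})
        if isinstance(deriv, bool):
            deriv = {"enabled": deriv}
        windows = d.get("windows", DEFAULT_WINDOWS)
        return cls(
            msc=d.get("msc", True),
            derivative=deriv.get("enabled", True),
            segment=deriv.get("segment", 5),
            gap=deriv.get("gap", 5),
            windows=tuple(map(tuple, windows)) if windows is not None else None,
        )


@dataclass(frozen=True)
class MSCReference:
    """Mean spectrum of a calibration set, on that set's grid."""

    grid: WavenumberGrid
    mean_spectrum: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mean_spectrum, dtype=float)
        if m.shape != (len(self.grid),):
            raise ValueError("reference length must match grid")
        object.__setattr__(self, "mean_spectrum", m)


def msc_fit(spectra: SpectraSet) -> MSCReference:
    """Fit the MSC reference: the pointwise mean of all spectra."""
    if spectra.n_samples < 2:
        raise ValueError("MSC reference requires >= 2 spectra")
    return MSCReference(spectra.grid, spectra.absorbance.mean(axis=0))


def _msc_coeffs(X: np.ndarray, ref: np.ndarray):
    """OLS of each row on [1, ref]; returns offsets a and slopes b."""
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom == 0.0:
        raise CorrectionError("constant MSC reference")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    a = X.mean(axis=1) - b * ref.mean()
    return a, b


def msc_apply(spectrum: np.ndarray, ref: MSCReference, *, tol: float = 1e-8):
    """Correct one spectrum: fit s = a + b*ref by OLS, return (s - a)/b."""
    s = np.atleast_2d(np.asarray(spectrum, dtype=float))
    a, b = _msc_coeffs(s, ref.mean_spectrum)
    if np.any(b <= 0) or np.any(np.abs(b) < tol):
        raise CorrectionError(
            "MSC slope non-positive or below tolerance (pathological spectrum)"
        )
    out = (s - a[:, None]) / b[:, None]
    return out[0] if np.asarray(spectrum).ndim == 1 else out


def gap_segment_first_derivative(
    spectrum: np.ndarray, grid: WavenumberGrid, segment: int = 5, gap: int = 5
):
    """Gap-segment (Norris-type) first derivative.

    Each point is first replaced by the centered moving average over
    ``segment`` points; the derivative at i is
    ``(smoothed[i+gap] - smoothed[i-gap]) / (2*gap*delta)`` with ``delta`` the
    nominal grid spacing.  Edge points without full support are dropped; the
    returned grid records the surviving wavenumbers.  Exact for affine
    spectra on a uniform grid.
    """
    if segment % 2 == 0 or segment < 1:
        raise ValueError("segment must be odd and >= 1")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    X = np.atleast_2d(np.asarray(spectrum, dtype=float))
    n = X.shape[1]
    if n < segment + 2 * gap:
        raise ValueError(
            f"spectrum length {n} too short for segment {segment}, gap {gap}"
        )
    half = segment // 2
    # centered moving average, valid region only
    kernel = np.ones(segment) / segment
    smoothed = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), 1, X
    )  # columns half .. n-1-half
    delta = float(grid.resolution)
    # smoothed column j corresponds to original index j + half
    deriv = (smoothed[:, 2 * gap :] - smoothed[:, : smoothed.shape[1] - 2 * gap]) / (
        2 * gap * delta
    )
    keep = np.arange(half + gap, n - half - gap)
    out_grid = WavenumberGrid(grid.values[keep], grid.resolution)
    out = deriv if np.asarray(spectrum).ndim > 1 else deriv[0]
    return out, out_grid


def apply_windows(spectra: SpectraSet, windows) -> SpectraSet:
    """Restrict to wavenumbers inside any closed [lo, hi] window."""
    v = spectra.grid.values
    mask = np.zeros(v.size, dtype=bool)
    for lo, hi in windows:
        mask |= (v >= lo) & (v <= hi)
    if not mask.any():
        raise ValueError("window masking removed every grid point")
    return SpectraSet(
        WavenumberGrid(v[mask], spectra.grid.resolution),
        spectra.absorbance[:, mask],
        list(spectra.sample_ids),
        spectra.meta,
    )


def preprocess(
    spectra: SpectraSet,
    config: PreprocessConfig,
    msc_ref: MSCReference | None = None,
) -> tuple[SpectraSet, MSCReference | None]:
    """Run the full pretreatment pipeline: MSC -> derivative -> windows.

    If MSC is enabled and no reference is supplied, one is fitted on the
    input (calibration use); the fitted/supplied reference is returned so it
    can be stored with the model and reused for prediction.  Pure function of
    (input, config, msc_ref).
    """
    X = spectra.absorbance
    grid = spectra.grid
    ref = None
    if config.msc:
        ref = msc_ref if msc_ref is not None else msc_fit(spectra)
        if not np.array_equal(ref.grid.values, grid.values):
            raise ValueError("MSC reference grid does not match input grid")
        X = msc_apply(X, ref)
    if config.derivative:
        X, grid = gap_segment_first_derivative(X, grid, config.segment, config.gap)
    out = SpectraSet(grid, X, list(spectra.sample_ids), spectra.meta)
    if config.windows is not None:
        out = apply_windows(out, config.windows)
    return out, ref
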