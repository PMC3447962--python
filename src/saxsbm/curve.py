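"""Scattering curves and the 3-column ASCII ``.dat`` dialect.

A curve is a momentum-transfer grid q (Å⁻¹), intensities I(q) in arbitrary
units, and, for experimental-style curves, per-point errors σ(q).  Files
are whitespace-delimited ``q  I  sigma`` columns; lines starting with ``#``
are comments.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = ["ScatteringCurve", "CurveFormatError", "read_curve", "write_curve"]


class CurveFormatError(ValueError):
    """Raised for malformed scattering-curve data or files."""


@dataclasses.dataclass
class ScatteringCurve:
    """q grid (strictly increasing, Å⁻¹), intensities, optional errors."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise CurveFormatError("q and intensity must be 1-D and equal length")
        if np.any(np.diff(self.q) <= 0):
            raise CurveFormatError("q grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise CurveFormatError("non-finite intensity")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise CurveFormatError("sigma length mismatch")
            if np.any(self.sigma <= 0) or not np.all(np.isfinite(self.sigma)):
                raise CurveFormatError("sigma must be finite and > 0")

    @property
    def n_points(self) -> int:
        return len(self.q)

    def same_grid(self, other: "ScatteringCurve", rtol: float = 1e-9) -> bool:
        return self.n_points == other.n_points and np.allclose(
            self.q, other.q, rtol=rtol, atol=0.0
        )


def read_curve(path: str | Path) -> ScatteringCurve:
    """Read a 3-column (or 2-column, no errors) ASCII curve file."""
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        fields = text.split()
        if len(fields) not in (2, 3):
            raise CurveFormatError(f"{path}:{lineno}: expected 2 or 3 columns")
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise CurveFormatError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise CurveFormatError(f"{path}: inconsistent column count")
    data = np.array(rows)
    sigma = data[:, 2] if ncol == 3 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sigma)


def write_curve(path: str | Path, curve: ScatteringCurve, header: str = "") -> None:
    """Write a curve with full double precision (round-trip safe)."""
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write("# q(1/A)  I(q)  sigma\n" if curve.sigma is not None else "# q(1/A)  I(q)\n")
        for i in range(curve.n_points):
            if curve.sigma is not None:
                fh.write(
                    f"{curve.q[i]:.17g} {curve.intensity[i]:.17g} {curve.sigma[i]:.17g}\n"
                )
            else:
                fh.write(f"{curve.q[i]:.17g} {curve.intensity[i]:.17g}\n")
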