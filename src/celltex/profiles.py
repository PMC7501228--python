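"""1D traces (intensity vs q or vs chi) with counting uncertainties.

A :class:`Profile1D` is the common currency between the image-reduction,
crystal-model and pole-figure layers.  Bins to which no pixel contributed
are *flagged* (``n_pixels == 0``, intensity ``NaN``), never zero-filled,
so that missing-wedge bins stay distinguishable from true zero intensity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, InvalidInput

__all__ = ["Profile1D"]


@dataclass
class Profile1D:
    """A 1D trace on a strictly increasing grid of bin centers.

    Parameters
    ----------
    axis:
        ``"q"`` (grid in 1/Angstrom) or ``"chi"`` (grid in degrees).
    grid:
        Bin centers, strictly increasing.
    intensity:
        Mean counts per bin (NaN where no pixel contributed).
    sigma:
        Poisson uncertainty of the bin mean.
    n_pixels:
        Number of contributing pixels per bin.
    meta:
        Free-form provenance (sector bounds, bands, checksums, ...).
    """

    axis: str
    grid: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    n_pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if self.axis not in ("q", "chi"):
            raise InvalidInput(f"axis must be 'q' or 'chi', got {self.axis!r}")
        n = self.grid.size
        if not (self.intensity.size == self.sigma.size == self.n_pixels.size == n):
            raise InvalidInput("profile arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.grid) > 0):
            raise InvalidInput("grid must be strictly increasing")
        if np.any(self.sigma[np.isfinite(self.sigma)] < 0):
            raise InvalidInput("sigma must be non-negative")

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of bins with no contributing pixels."""
        return self.n_pixels == 0

    @property
    def valid(self) -> np.ndarray:
        return (self.n_pixels > 0) & np.isfinite(self.intensity)

    def same_grid(self, other: "Profile1D", atol: float = 1e-9) -> bool:
        return (
            self.axis == other.axis
            and self.grid.size == other.grid.size
            and bool(np.allclose(self.grid, other.grid, atol=atol))
        )

    def require_same_grid(self, other: "Profile1D") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"profiles have different grids ({self.axis}[{self.grid.size}] "
                f"vs {other.axis}[{other.grid.size}])"
            )

    # ---------------------------------------------------------------- CSV I/O
    def to_csv(self, path) -> None:
        """Write as CSV with '#'-prefixed header comments carrying metadata."""
        buf = io.StringIO()
        buf.write(f"# axis: {self.axis}\n")
        for key, value in sorted(self.meta.items()):
            buf.write(f"# {key}: {value}\n")
        buf.write("axis_value,intensity,sigma,n_pixels\n")
        for x, i, s, n in zip(self.grid, self.intensity, self.sigma, self.n_pixels):
            buf.write(f"{x:.10g},{i:.10g},{s:.10g},{n:d}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "Profile1D":
        axis = "q"
        meta: dict = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if ":" in body:
                        key, value = body.split(":", 1)
                        key, value = key.strip(), value.strip()
                        if key == "axis":
                            axis = value
                        else:
                            meta[key] = value
                    continue
                if line.startswith("axis_value"):
                    continue
                parts = line.split(",")
                rows.append([float(parts[0]), float(parts[1]), float(parts[2]), int(parts[3])])
        arr = np.array(rows, dtype=float)
        return cls(
            axis=axis,
            grid=arr[:, 0],
            intensity=arr[:, 1],
            sigma=arr[:, 2],
            n_pixels=arr[:, 3].astype(int),
            meta=meta,
        )
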