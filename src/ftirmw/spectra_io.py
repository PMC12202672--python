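"""Reading, writing and validating labelled IR absorbance spectra.

Spectra are stored with the wavenumber axis *descending* (4000 -> 500 1/cm),
mirroring the convention of FTIR instruments; files with an ascending axis are
accepted and flipped on ingestion.  All downstream operations address points by
wavenumber value, never by array position.

The canonical interchange format is a plain CSV with the wavenumber in the
first column and one replicate spectrum per subsequent column; the column
header carries the replicate identity as ``<sample>:<replicate>``.  Sample
labels (weight-average molecular weight from SEC, optional dispersity) live in
a separate two/three-column CSV.  JCAMP-DX files with AFFN-encoded
``##XYDATA=(X++(Y..Y))`` blocks can be read but not written.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SampleLabel",
    "LabelledDataset",
    "SpectraParseError",
    "read_spectra",
    "write_spectra",
    "read_labels",
    "write_labels",
    "resample_to_grid",
    "average_replicates",
    "validation_report",
    "mw_to_mn",
]


class SpectraParseError(ValueError):
    """Raised when a spectra file violates the format contract."""


@dataclass(frozen=True)
class Spectrum:
    """One replicate IR measurement.

    Parameters
    ----------
    sample_id, replicate_id : str
        Identity of the physical sample and of the repeat measurement.
    wavenumbers : ndarray
        Strictly monotone wavenumber axis in 1/cm.  Stored descending.
    absorbances : ndarray
        Dimensionless absorbance, same length as ``wavenumbers``.  Negative
        values are allowed (baseline noise) but flagged by
        :func:`validation_report`.
    """

    sample_id: str
    replicate_id: str
    wavenumbers: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise ValueError("wavenumbers and absorbances must be 1-D and of equal length")
        if w.size == 0:
            raise ValueError("empty spectrum")
        d = np.diff(w)
        if np.any(d == 0):
            idx = int(np.nonzero(d == 0)[0][0])
            raise SpectraParseError(f"duplicate wavenumber {w[idx]!r}")
        if not (np.all(d > 0) or np.all(d < 0)):
            idx = int(np.nonzero(np.sign(d) != np.sign(d[0]))[0][0]) + 1
            raise SpectraParseError(f"non-monotone wavenumber grid at row {idx} (nu={w[idx]!r})")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbances must be finite")
        if w.size > 1 and d[0] > 0:  # stored descending by convention
            w, a = w[::-1], a[::-1]
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbances", a)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def index_of(self, nu: float, atol: float = 1e-6) -> int:
        """Array position of wavenumber ``nu``; KeyError if absent."""
        hits = np.nonzero(np.isclose(self.wavenumbers, nu, rtol=0.0, atol=atol))[0]
        if hits.size == 0:
            raise KeyError(f"wavenumber {nu} not on grid")
        return int(hits[0])


@dataclass(frozen=True)
class SampleLabel:
    """SEC label for one sample: weight-average molecular weight, optional dispersity."""

    sample_id: str
    mw_weight_avg: float
    dispersity: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mw_weight_avg) or self.mw_weight_avg <= 0:
            raise ValueError("mw_weight_avg must be finite and positive")
        if self.dispersity is not None and self.dispersity < 1.0:
            raise ValueError("dispersity must be >= 1")

    @property
    def mw_number_avg(self) -> float | None:
        """Number-average molecular weight M_n = M_w / dispersity, if dispersity is known."""
        if self.dispersity is None:
            return None
        return mw_to_mn(self.mw_weight_avg, self.dispersity)


@dataclass
class LabelledDataset:
    """Replicate spectra grouped by sample, each sample carrying an M_w label."""

    spectra: list[Spectrum]
    labels: dict[str, SampleLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.spectra:
            if s.sample_id not in self.labels:
                raise ValueError(f"spectrum {s.sample_id}:{s.replicate_id} has no label")

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.sample_id, None)
        return list(seen)

    def common_grid(self) -> np.ndarray:
        """The shared wavenumber grid; raises if spectra disagree."""
        grid = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
                raise ValueError(
                    f"spectrum {s.sample_id}:{s.replicate_id} is not on the common grid; "
                    "resample explicitly with resample_to_grid"
                )
        return grid

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
        """Stack spectra into an (n_spectra, n_wavenumbers) absorbance matrix.

        Returns ``(wavenumbers, matrix, sample_ids, replicate_ids)`` with rows
        in dataset order.
        """
        grid = self.common_grid()
        mat = np.vstack([s.absorbances for s in self.spectra])
        return grid, mat, [s.sample_id for s in self.spectra], [s.replicate_id for s in self.spectra]

    def mw_targets(self) -> np.ndarray:
        """Per-spectrum M_w target vector (Da), aligned with :meth:`to_matrix` rows."""
        return np.array([self.labels[s.sample_id].mw_weight_avg for s in self.spectra])

    def replicates(self, sample_id: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.sample_id == sample_id]


# ---------------------------------------------------------------------------
# file I/O


def _split_column_name(name: str) -> tuple[str, str]:
    if ":" in name:
        sample, rep = name.split(":", 1)
        return sample.strip(), rep.strip()
    return name.strip(), "0"


def read_spectra(path: str | Path, format: str = "csv") -> list[Spectrum]:
    """Read replicate spectra from a CSV or JCAMP-DX file.

    CSV dialect: first column is the wavenumber (1/cm), each further column is
    one replicate named ``<sample>:<replicate>`` in the header row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_spectra_csv(path)
    if format == "jcamp_dx":
        return _read_spectra_jcamp(path)
    raise ValueError(f"unknown format {format!r}")


def _read_spectra_csv(path: Path) -> list[Spectrum]:
    # round_trip parsing so write_spectra -> read_spectra is the identity
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SpectraParseError("need a wavenumber column and at least one spectrum column")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise SpectraParseError(f"mismatched column lengths / missing values in columns {bad}")
    w = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        sample, rep = _split_column_name(str(col))
        out.append(Spectrum(sample, rep, w.copy(), df[col].to_numpy(dtype=float)))
    return out


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _read_spectra_jcamp(path: Path) -> list[Spectrum]:
    """Minimal read-only JCAMP-DX parser for AFFN ``(X++(Y..Y))`` tables."""
    title = path.stem
    xfactor = yfactor = 1.0
    deltax = None
    xs: list[float] = []
    ys: list[float] = []
    in_table = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.replace(" ", "").upper()
            value = value.strip()
            if key == "TITLE":
                title = value or title
            elif key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "DELTAX":
                deltax = float(value)
            elif key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise SpectraParseError(f"unsupported XYDATA form {value!r}")
                in_table = True
            elif key == "END":
                in_table = False
            continue
        if not in_table:
            continue
        nums = [float(t) for t in _JCAMP_NUM.findall(line)]
        if len(nums) < 2:
            raise SpectraParseError(f"malformed XYDATA line: {raw!r}")
        x0, yvals = nums[0], nums[1:]
        if deltax is None and len(yvals) > 1:
            raise SpectraParseError("multi-Y lines require ##DELTAX")
        step = deltax if deltax is not None else 0.0
        for k, y in enumerate(yvals):
            xs.append((x0 + k * step) * xfactor)
            ys.append(y * yfactor)
    if not xs:
        raise SpectraParseError("no XYDATA block found")
    return [Spectrum(title, "0", np.array(xs), np.array(ys))]


def write_spectra(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra sharing a common grid to the canonical CSV layout.

    Values are written with shortest round-trip ``repr`` so that
    ``read_spectra(write_spectra(s))`` reproduces the floats exactly.
    """
    if not spectra:
        raise ValueError("nothing to write")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise ValueError("all spectra must share one grid to be written together")
    cols = {"wavenumber_cm-1": grid}
    for s in spectra:
        cols[f"{s.sample_id}:{s.replicate_id}"] = s.absorbances
    pd.DataFrame(cols).to_csv(path, index=False)


def read_labels(path: str | Path) -> dict[str, SampleLabel]:
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    labels = {}
    for _, row in df.iterrows():
        disp = row.get("dispersity")
        disp = None if disp is None or (isinstance(disp, float) and np.isnan(disp)) else float(disp)
        labels[str(row["sample_id"])] = SampleLabel(str(row["sample_id"]), float(row["mw_da"]), disp)
    return labels


def write_labels(labels: Mapping[str, SampleLabel], path: str | Path) -> None:
    rows = [
        {"sample_id": lab.sample_id, "mw_da": lab.mw_weight_avg, "dispersity": lab.dispersity}
        for lab in labels.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid and replicate operations


def resample_to_grid(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate ``s`` onto ``grid`` (no extrapolation)."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    lo, hi = s.wavenumbers.min(), s.wavenumbers.max()
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] extends outside the measured range [{lo}, {hi}]"
        )
    asc_w = s.wavenumbers[::-1]  # stored descending
    asc_a = s.absorbances[::-1]
    interp = np.interp(grid, asc_w, asc_a)
    return Spectrum(s.sample_id, s.replicate_id, grid, interp)


def average_replicates(spectra: Iterable[Spectrum], sample_id: str) -> Spectrum:
    """Pointwise mean of the replicates of one sample (for plotting/diagnostics)."""
    chosen = [s for s in spectra if s.sample_id == sample_id]
    if not chosen:
        raise ValueError(f"no replicates for sample {sample_id!r}")
    grid = chosen[0].wavenumbers
    for s in chosen[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise ValueError("replicates must share the wavenumber grid")
    mean = np.mean([s.absorbances for s in chosen], axis=0)
    return Spectrum(sample_id, "mean", grid.copy(), mean)


def validation_report(spectra: Iterable[Spectrum]) -> pd.DataFrame:
    """Per-spectrum sanity summary; negative absorbances are flagged, not rejected."""
    rows = []
    for s in spectra:
        rows.append(
            {
                "sample_id": s.sample_id,
                "replicate_id": s.replicate_id,
                "n_points": len(s),
                "nu_min": float(s.wavenumbers.min()),
                "nu_max": float(s.wavenumbers.max()),
                "n_negative": int(np.sum(s.absorbances < 0)),
                "has_negative": bool(np.any(s.absorbances < 0)),
            }
        )
    return pd.DataFrame(rows)


def mw_to_mn(mw: float, dispersity: float) -> float:
    """Number-average molecular weight from M_w and dispersity: M_n = M_w / Đ.

    With Đ = M_w / M_n >= 1 by definition; e.g. M_w = 4060 Da at Đ = 2 gives
    M_n = 2030 Da.
    """
    if dispersity < 1.0:
        raise ValueError(f"dispersity must be >= 1, got {dispersity}")
    if not np.isfinite(mw) or mw <= 0:
        raise ValueError("mw must be finite and positive")
    return mw / dispersity
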