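"""Co-registered embryo profile sets.

An :class:`EmbryoDataset` bundles the one-dimensional fields measured (or
synthesised) along the anterior-posterior (AP) axis of a single embryo:
flow velocity v, compression rate -dv/dx, nematic order Q, myosin
concentration c and, optionally, the outer ingression distance u.  All
fields share one strictly increasing spatial grid x (micrometres, embryo
centre at 0; anterior negative).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

_CSV_COLUMNS = ("x_um", "v_um_per_min", "dvdx_per_min", "Q", "c", "u_um")


@dataclasses.dataclass
class EmbryoDataset:
    """Profiles for one embryo (or one condition-average) on a common AP grid.

    Parameters
    ----------
    x : array, micrometres
    v : array, micrometres/minute (positive = toward posterior)
    dvdx : array, 1/minute; note the *compression rate* is ``-dvdx``
    Q : array, dimensionless nematic order (Q = -Qxx)
    c : array or None, myosin concentration in arbitrary units, >= 0
    u : array or None, outer ingression distance, micrometres, >= 0
    noise_sigma_Q : float, standard deviation of the Gaussian noise added to
        Q when the dataset was synthesised (0 for measured data)
    truth : GelParameters or None, generating parameters when known
    """

    x: np.ndarray
    v: np.ndarray
    dvdx: np.ndarray
    Q: np.ndarray
    c: np.ndarray | None = None
    u: np.ndarray | None = None
    noise_sigma_Q: float = 0.0
    truth: object | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1 or self.x.size < 2:
            raise InvalidParameterError("x must be a 1-D grid with >= 2 points")
        if np.any(np.diff(self.x) <= 0):
            raise InvalidParameterError("x must be strictly increasing")
        for name in ("v", "dvdx", "Q", "c", "u"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.x.shape:
                raise InvalidParameterError(
                    f"{name} must share the grid of x (shape {self.x.shape})"
                )
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "x_um": self.x,
            "v_um_per_min": self.v,
            "dvdx_per_min": self.dvdx,
            "Q": self.Q,
            "c": self.c if self.c is not None else np.full_like(self.x, np.nan),
            "u_um": self.u if self.u is not None else np.full_like(self.x, np.nan),
        }
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "EmbryoDataset":
        missing = [c for c in _CSV_COLUMNS[:4] if c not in frame.columns]
        if missing:
            raise InvalidParameterError(f"missing columns: {missing}")
        c = frame["c"].to_numpy() if "c" in frame.columns else None
        if c is not None and np.all(np.isnan(c)):
            c = None
        u = frame["u_um"].to_numpy() if "u_um" in frame.columns else None
        if u is not None and np.all(np.isnan(u)):
            u = None
        return cls(
            x=frame["x_um"].to_numpy(),
            v=frame["v_um_per_min"].to_numpy(),
            dvdx=frame["dvdx_per_min"].to_numpy(),
            Q=frame["Q"].to_numpy(),
            c=c,
            u=u,
            **kwargs,
        )

    def save_csv(self, path: str | Path, truth_sidecar: bool = True) -> None:
        """Write profiles as CSV; ground truth, if present, as a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if truth_sidecar and self.truth is not None:
            sidecar = path.with_suffix(".truth.json")
            payload = dataclasses.asdict(self.truth)
            payload["noise_sigma_Q"] = self.noise_sigma_Q
            sidecar.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load_csv(cls, path: str | Path) -> "EmbryoDataset":
        path = Path(path)
        ds = cls.from_frame(pd.read_csv(path))
        sidecar = path.with_suffix(".truth.json")
        if sidecar.exists():
            from .gel import GelParameters

            payload = json.loads(sidecar.read_text())
            ds.noise_sigma_Q = payload.pop("noise_sigma_Q", 0.0)
            ds.truth = GelParameters(**payload)
        return ds


def average_datasets(datasets: list[EmbryoDataset]) -> EmbryoDataset:
    """Pointwise average of co-registered embryo datasets (common grid required)."""
    if not datasets:
        raise InvalidParameterError("no datasets to average")
    x = datasets[0].x
    for ds in datasets[1:]:
        if ds.x.shape != x.shape or not np.allclose(ds.x, x):
            raise InvalidParameterError("datasets must share one grid")

    def _mean(name: str) -> np.ndarray | None:
        arrays = [getattr(ds, name) for ds in datasets]
        if any(a is None for a in arrays):
            return None
        return np.mean(arrays, axis=0)

    return EmbryoDataset(
        x=x,
        v=_mean("v"),
        dvdx=_mean("dvdx"),
        Q=_mean("Q"),
        c=_mean("c"),
        u=_mean("u"),
        noise_sigma_Q=datasets[0].noise_sigma_Q / np.sqrt(len(datasets)),
        truth=datasets[0].truth,
    )
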