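"""Parameter sweeps and batch evaluation of the three biplane estimators.

:func:`run_sweep` reproduces the synthetic error study: over a grid of
basal slanting angles bθ, view orientations Am, viewing angles vθ and
eccentricities μ it builds the paraboloid phantom, extracts the two
analytic view contours, runs SBR / TBC / BOD and records percentage errors
against the analytic ground truth.  :func:`run_mesh_batch` does the same
for a directory of surface meshes with supplied landmarks, using the mesh
volume as truth.  Both are deterministic: rerunning a configuration yields
byte-identical CSV output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators, mesh_io
from .geometry import Contour2D
from .slicing import slice_contour, standard_view_planes
from .synthetic import ParaboloidSpec, ViewConfig, truth_volume, view_pair

__all__ = [
    "ErrorRecord",
    "SweepConfig",
    "run_sweep",
    "run_mesh_batch",
    "slant_prevalence",
    "records_to_frame",
    "summarize",
]

log = logging.getLogger(__name__)

METHODS = {
    "SBR": estimators.sbr_volume,
    "TBC": estimators.tbc_volume,
    "BOD": estimators.bod_volume,
}

# fixed column order for byte-stable CSV output
RECORD_COLUMNS = [
    "method", "b_theta", "Am", "v_theta", "mu",
    "V_est", "V_true", "pct_error", "abs_error_mL", "error",
]


@dataclass(frozen=True)
class ErrorRecord:
    """One evaluation of one method on one geometry."""

    method: str
    b_theta: float
    Am: float
    v_theta: float
    mu: float
    V_est: float       # mL
    V_true: float      # mL
    error: str = ""    # non-empty when the evaluation failed

    @property
    def pct_error(self) -> float:
        if not np.isfinite(self.V_est) or self.V_true <= 0:
            return float("nan")
        return 100.0 * (self.V_est - self.V_true) / self.V_true

    @property
    def abs_error_mL(self) -> float:
        return self.V_est - self.V_true


@dataclass(frozen=True)
class SweepConfig:
    """Grid definition for the synthetic error study.

    Defaults cover the reported sweeps: bθ from 0° to 20°, Am from 0° to
    90°, vθ ∈ {60°, 75°, 90°}, μ = 1.1, with the default phantom
    dimensions (A = 25 mm, H0 = 80 mm) and n = 20 disks.
    """

    b_theta_deg: tuple = tuple(range(0, 21))
    Am_deg: tuple = (0.0, 90.0)
    v_theta_deg: tuple = (60.0, 75.0, 90.0)
    mu: tuple = (1.1,)
    methods: tuple = ("SBR", "TBC", "BOD")
    base_major_semiaxis: float = 25.0
    length: float = 80.0
    n_disks: int = 20
    n_contour_points: int = 257

    def __post_init__(self):
        for name, grid in (("b_theta_deg", self.b_theta_deg),
                           ("Am_deg", self.Am_deg),
                           ("v_theta_deg", self.v_theta_deg),
                           ("mu", self.mu)):
            if len(grid) == 0:
                raise ValueError(f"empty grid: {name}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def run_sweep(config: SweepConfig = SweepConfig()) -> list[ErrorRecord]:
    """Evaluate every method at every grid point of the synthetic study.

    Per grid point the phantom's cutting plane is solved so both view
    azimuths see in-plane slant bθ (the workbench convention), the two
    analytic contours are extracted at the configured azimuths, and each
    method's volume is compared with the quadrature ground truth.
    Evaluation errors are captured in the record's ``error`` field; the
    sweep never aborts.
    """
    records: list[ErrorRecord] = []
    for mu in config.mu:
        for b in config.b_theta_deg:
            for Am in config.Am_deg:
                for vth in config.v_theta_deg:
                    view = ViewConfig(Am, vth)
                    try:
                        spec = ParaboloidSpec.for_view_slant(
                            b, view,
                            base_major_semiaxis=config.base_major_semiaxis,
                            eccentricity=mu, length=config.length)
                        v_true = truth_volume(spec)
                        cA, cB = view_pair(spec, view,
                                           config.n_contour_points)
                    except Exception as exc:  # noqa: BLE001
                        for m in config.methods:
                            records.append(ErrorRecord(
                                m, b, Am, vth, mu, float("nan"),
                                float("nan"), error=str(exc)))
                        continue
                    for m in config.methods:
                        try:
                            est = METHODS[m](cA, cB, n=config.n_disks)
                            records.append(ErrorRecord(
                                m, b, Am, vth, mu,
                                est.total_volume, v_true))
                        except Exception as exc:  # noqa: BLE001
                            records.append(ErrorRecord(
                                m, b, Am, vth, mu, float("nan"), v_true,
                                error=str(exc)))
    return records


def records_to_frame(records: list[ErrorRecord]) -> pd.DataFrame:
    """Records as a DataFrame with a fixed, documented column order."""
    rows = [{
        "method": r.method, "b_theta": r.b_theta, "Am": r.Am,
        "v_theta": r.v_theta, "mu": r.mu, "V_est": r.V_est,
        "V_true": r.V_true, "pct_error": r.pct_error,
        "abs_error_mL": r.abs_error_mL, "error": r.error,
    } for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize(records: list[ErrorRecord]) -> pd.DataFrame:
    """Bias (mean pct error) and precision (SD) per method."""
    frame = records_to_frame([r for r in records if not r.error])
    out = (frame.groupby("method")["pct_error"]
           .agg(bias="mean", precision="std", n="count")
           .reset_index())
    return out


# ---------------------------------------------------------------------------
# mesh batches


def _read_landmarks(path) -> pd.DataFrame:
    lm = pd.read_csv(path)
    required = {"mesh", "apex_x", "apex_y", "apex_z",
                "base_x", "base_y", "base_z", "rv_x", "rv_y", "rv_z"}
    missing = required - set(lm.columns)
    if missing:
        raise ValueError(f"landmarks file lacks columns: {sorted(missing)}")
    return lm


def run_mesh_batch(mesh_dir, landmarks_file, second_view: str = "A3C",
                   methods: tuple = ("SBR", "TBC", "BOD"),
                   n_disks: int = 20) -> tuple[list[ErrorRecord], pd.DataFrame]:
    """Evaluate the estimators on a directory of closed LV meshes.

    Landmarks (apex, base center, RV direction) come from a sidecar CSV
    with columns ``mesh, apex_x..z, base_x..z, rv_x..z``.  The primary view
    is the A4C; ``second_view`` chooses A2C (vθ≈60°) or A3C (vθ=90°).
    Truth is the mesh volume; per-mesh failures are logged, recorded with
    the failure message, and skipped.
    """
    if second_view not in ("A2C", "A3C"):
        raise ValueError("second_view must be 'A2C' or 'A3C'")
    mesh_dir = Path(mesh_dir)
    lm = _read_landmarks(landmarks_file)
    records: list[ErrorRecord] = []
    for row in lm.itertuples(index=False):
        name = str(row.mesh)
        try:
            mesh = mesh_io.read_mesh(mesh_dir / name)
            v_true = mesh_io.mesh_volume(mesh)
            frames = standard_view_planes(
                [row.base_x, row.base_y, row.base_z],
                [row.apex_x, row.apex_y, row.apex_z],
                [row.rv_x, row.rv_y, row.rv_z])
            cA = slice_contour(mesh, frames["A4C"])
            cB = slice_contour(mesh, frames[second_view])
        except Exception as exc:  # noqa: BLE001
            log.warning("skipping %s: %s", name, exc)
            for m in methods:
                records.append(ErrorRecord(
                    m, float("nan"), float("nan"), float("nan"),
                    float("nan"), float("nan"), float("nan"),
                    error=f"{name}: {exc}"))
            continue
        b_view = abs(estimators.slant_angle(cA))
        vth = 90.0 if second_view == "A3C" else 60.0
        for m in methods:
            try:
                est = METHODS[m](cA, cB, n=n_disks)
                records.append(ErrorRecord(
                    m, b_view, float("nan"), vth, float("nan"),
                    est.total_volume, v_true))
            except Exception as exc:  # noqa: BLE001
                records.append(ErrorRecord(
                    m, b_view, float("nan"), vth, float("nan"),
                    float("nan"), v_true, error=f"{name}: {exc}"))
    if not records:
        log.warning("no meshes found in %s", mesh_dir)
    return records, summarize(records)


def slant_prevalence(slants, threshold_deg: float = 12.0) -> float:
    """Fraction of cases whose in-plane basal slant exceeds the threshold.

    Accepts an iterable of angles in degrees or of contours (whose
    ``slant_angle_deg`` is used); magnitudes are compared.
    """
    if threshold_deg < 0:
        raise ValueError("threshold must be >= 0")
    values = [abs(s.slant_angle_deg) if isinstance(s, Contour2D) else abs(s)
              for s in slants]
    if not values:
        raise ValueError("no slant values supplied")
    return float(np.mean([v > threshold_deg for v in values]))
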