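"""File-level workflow: metadata tables, series measurement, reports.

The on-disk layout of a binding study is a directory of two-column text
chromatograms plus one metadata CSV with columns

    file, analyte, concentration_mM, injection_volume_uL,
    flow_rate_mL_min, wavelength_nm

Measurement reads each trace, locates the analyte apex, converts it to a
capacity factor against the supplied void time, and assembles one
:class:`~affinichrom.binding.InjectionSeries` per analyte ready for
:func:`~affinichrom.binding.analyze_series`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import BindingFit, Injection, InjectionSeries, analyze_series
from .chromatogram import detect_apex, read_chromatogram, write_chromatogram
from .column import ColumnSystem
from .errors import ValidationError
from .simulate import SimulationTruth, generate_series, generate_void_marker

META_COLUMNS = [
    "file",
    "analyte",
    "concentration_mM",
    "injection_volume_uL",
    "flow_rate_mL_min",
    "wavelength_nm",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata table missing columns: {missing}")
    return df


def measure_series(
    metadata_csv: str | Path, t0: float, flow_rate: float
) -> dict[str, InjectionSeries]:
    """Measure every chromatogram in a study and group into series."""
    meta = read_metadata(metadata_csv)
    base = Path(metadata_csv).parent
    column = ColumnSystem(t0=t0, flow_rate=flow_rate)
    series: dict[str, InjectionSeries] = {}
    for analyte, group in meta.groupby("analyte", sort=False):
        injections = []
        for row in group.itertuples(index=False):
            chrom = read_chromatogram(base / row.file)
            peak = detect_apex(chrom)
            k = column.capacity_factor(peak.apex_time)
            injections.append(
                Injection(
                    concentration=row.concentration_mM * 1e-3,
                    volume=row.injection_volume_uL * 1e-6,
                    t_r=peak.apex_time,
                    k=k,
                )
            )
        series[str(analyte)] = InjectionSeries(
            analyte=str(analyte), column=column, injections=injections
        )
    return series


def analyze_study(
    metadata_csv: str | Path, t0: float, flow_rate: float
) -> dict[str, BindingFit]:
    """measure_series followed by analyze_series for each analyte."""
    return {
        name: analyze_series(s)
        for name, s in measure_series(metadata_csv, t0, flow_rate).items()
    }


def fit_to_dict(fit: BindingFit) -> dict:
    """JSON-ready summary of a binding fit."""
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r": fit.r,
        "r2": fit.r2,
        "se_slope": fit.se_slope,
        "se_intercept": fit.se_intercept,
        "K_A": fit.K_A,
        "n_a": fit.n_a,
        "se_K_A": fit.se_K_A,
        "n_points": fit.n_points,
        "monotonicity_violated": fit.monotonicity_violated,
    }


def fit_points_table(analyte: str, fit: BindingFit) -> pd.DataFrame:
    """Per-point report mirroring the linearized plot: x, y, fit, residual."""
    x = np.array([p.x for p in fit.points])
    y = np.array([p.y for p in fit.points])
    fitted = fit.slope * x + fit.intercept
    return pd.DataFrame(
        {
            "analyte": analyte,
            "x": x,
            "y": y,
            "fitted_y": fitted,
            "residual": y - fitted,
        }
    )


def write_synthetic_study(
    out_dir: str | Path,
    truth: SimulationTruth,
    concentrations,
    injection_volume: float,
    *,
    analyte: str = "synthetic",
    wavelength_nm: float = 330.0,
    dt: float = 0.002,
) -> Path:
    """Render a synthetic study to disk in the layout measure_series reads.

    Writes one chromatogram text file per concentration, a void-marker
    trace, the metadata CSV, and truth.json with the generating
    parameters. Returns the metadata CSV path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, traces, _ = generate_series(
        truth,
        concentrations,
        injection_volume,
        with_traces=True,
        dt=dt,
        analyte=analyte,
    )
    rows = []
    for inj, trace in zip(series.injections, traces):
        fname = f"{analyte}_{inj.concentration * 1e3:.1f}mM.csv"
        write_chromatogram(trace, out / fname)
        rows.append(
            {
                "file": fname,
                "analyte": analyte,
                "concentration_mM": inj.concentration * 1e3,
                "injection_volume_uL": inj.volume * 1e6,
                "flow_rate_mL_min": truth.column.flow_rate,
                "wavelength_nm": wavelength_nm,
            }
        )
    write_chromatogram(generate_void_marker(truth, dt=dt), out / "void_marker.csv")
    meta_path = out / "series.csv"
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(meta_path, index=False)
    (out / "truth.json").write_text(
        json.dumps(
            {
                "K_A": truth.K_A,
                "n_a": truth.n_a,
                "t0_min": truth.column.t0,
                "flow_rate_mL_min": truth.column.flow_rate,
                "void_volume_L": truth.column.void_volume,
                "sigma_min": truth.sigma,
                "tau_min": truth.tau,
                "baseline": truth.baseline,
                "height_scale": truth.height_scale,
                "rel_sd_tr": truth.rel_sd_tr,
                "detector_sd": truth.detector_sd,
                "seed": truth.seed,
            },
            indent=2,
        )
    )
    return meta_path
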