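"""Delimited-text readers/writers and the experiment manifest.

All on-disk formats are plain text:

* MWD file — two whitespace/tab-separated columns (molecular weight g/mol,
  density) with ``#``-prefixed header lines carrying ``label``,
  ``abscissa_convention`` and units.  Values round-trip bit-identically
  (written with 17 significant digits).
* Chromatogram file — two columns (time min, signal), optional header.
* Standards file — two columns (molecular_weight g/mol, retention_time min).
* Calibration file — JSON with coefficients, degree, validity window,
  standards, residual RMS.
* Manifest — YAML describing one fractionation experiment: parent file and
  mass, fraction files/masses/labels, scheme breakpoints, tolerances.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCurve, Chromatogram
from .fractionation import (
    FractionSample,
    FractionationExperiment,
    IntervalReport,
    IntervalScheme,
)
from .mwd import MWDistribution

__all__ = [
    "read_mwd",
    "write_mwd",
    "read_chromatogram",
    "write_chromatogram",
    "read_standards",
    "write_standards",
    "read_calibration",
    "write_calibration",
    "read_manifest",
    "write_manifest",
    "write_report",
]

_FLOAT_FMT = "%.17g"


def _read_two_columns(path: str | Path) -> tuple[dict[str, str], np.ndarray, np.ndarray]:
    meta: dict[str, str] = {}
    col0, col1 = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            try:
                a, b = float(parts[0]), float(parts[1])
            except ValueError:
                # tolerate a single non-numeric header row
                if not col0:
                    continue
                raise
            col0.append(a)
            col1.append(b)
    if len(col0) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    return meta, np.array(col0), np.array(col1)


def read_mwd(path: str | Path) -> MWDistribution:
    meta, grid, density = _read_two_columns(path)
    return MWDistribution(
        label=meta.get("label", Path(path).stem),
        grid=grid,
        density=density,
        abscissa_convention=meta.get("abscissa_convention", "log10_M"),
    )


def write_mwd(dist: MWDistribution, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label: {dist.label}\n")
        fh.write(f"# abscissa_convention: {dist.abscissa_convention}\n")
        fh.write("# columns: molecular_weight_g_per_mol\tdensity\n")
        for m, d in zip(dist.grid, dist.density):
            fh.write(f"{m:.17g}\t{d:.17g}\n")


def read_chromatogram(path: str | Path) -> Chromatogram:
    meta, time, signal = _read_two_columns(path)
    return Chromatogram(
        label=meta.get("label", Path(path).stem), time=time, signal=signal
    )


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label: {chrom.label}\n")
        fh.write("# columns: time_min\tsignal\n")
        for t, s in zip(chrom.time, chrom.signal):
            fh.write(f"{t:.17g}\t{s:.17g}\n")


def read_standards(path: str | Path) -> list[tuple[float, float]]:
    """Calibration standards: (molecular weight g/mol, retention time min)."""
    _, mw, rt = _read_two_columns(path)
    return list(zip(mw.tolist(), rt.tolist()))


def write_standards(standards, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: molecular_weight_g_per_mol\tretention_time_min\n")
        for m, t in standards:
            fh.write(f"{m:.17g}\t{t:.17g}\n")


def write_calibration(cal: CalibrationCurve, path: str | Path) -> None:
    payload = {
        "coefficients": list(cal.coefficients),
        "degree": cal.degree,
        "time_valid_min": cal.time_valid_min,
        "time_valid_max": cal.time_valid_max,
        "standards": [list(s) for s in cal.standards],
        "fit_residual_rms": cal.fit_residual_rms,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_calibration(path: str | Path) -> CalibrationCurve:
    payload = json.loads(Path(path).read_text())
    return CalibrationCurve(
        coefficients=np.array(payload["coefficients"]),
        degree=int(payload["degree"]),
        time_valid_min=float(payload["time_valid_min"]),
        time_valid_max=float(payload["time_valid_max"]),
        standards=[tuple(s) for s in payload.get("standards", [])],
        fit_residual_rms=float(payload.get("fit_residual_rms", 0.0)),
    )


def read_manifest(path: str | Path) -> dict[str, Any]:
    """Parse and validate an experiment manifest (paths resolved relative
    to the manifest's directory)."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict) or "parent" not in cfg or "fractions" not in cfg:
        raise ValueError(f"{path}: manifest must define 'parent' and 'fractions'")
    if not cfg["fractions"]:
        raise ValueError(f"{path}: manifest lists no fractions")
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    cfg["parent"]["file"] = resolve(cfg["parent"]["file"])
    for fr in cfg["fractions"]:
        fr["file"] = resolve(fr["file"])
    for key in ("parent", *range(len(cfg["fractions"]))):
        entry = cfg["parent"] if key == "parent" else cfg["fractions"][key]
        if not Path(entry["file"]).exists():
            raise FileNotFoundError(f"{path}: referenced file {entry['file']} missing")
        if float(entry["mass_g"]) < 0:
            raise ValueError(f"{path}: negative mass for {entry.get('label', key)}")
    return cfg


def write_manifest(cfg: dict[str, Any], path: str | Path) -> None:
    out = json.loads(json.dumps(cfg, default=str))  # stringify Paths
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def load_experiment(cfg: dict[str, Any]) -> FractionationExperiment:
    """Build a :class:`FractionationExperiment` from a parsed manifest."""
    parent = read_mwd(cfg["parent"]["file"])
    if "label" in cfg["parent"]:
        parent.label = cfg["parent"]["label"]
    fractions = []
    for fr in cfg["fractions"]:
        dist = read_mwd(fr["file"])
        label = fr.get("label", dist.label)
        dist.label = label
        fractions.append(FractionSample(dist, float(fr["mass_g"]), label))
    return FractionationExperiment(
        parent=parent, m0=float(cfg["parent"]["mass_g"]), fractions=fractions
    )


def scheme_from_manifest(cfg: dict[str, Any]) -> IntervalScheme:
    scheme = cfg.get("scheme", ["min", "max"])
    if isinstance(scheme, str):
        return IntervalScheme.from_string(scheme)
    return IntervalScheme(list(scheme))


def write_report(
    report: IntervalReport, out_dir: str | Path, stem: str = "interval_report"
) -> dict[str, Path]:
    """Write the long-format delimited table, balance table, and JSON mirror.

    The delimited tables round percentages to 1 d.p. and R to 2 d.p. (the
    conventional reporting precision); the JSON mirror keeps full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}.tsv"
    bal = out_dir / f"{stem}_balance.tsv"
    js = out_dir / f"{stem}.json"

    table = report.table.copy()
    for col in ("composition_pct", "yield_total_pct", "interval_yield_pct"):
        if col in table:
            table[col] = table[col].round(1)
    for col in ("ratio_R", "r_bound"):
        if col in table:
            table[col] = table[col].round(2)
    if "interval_mass_g" in table:
        table["interval_mass_g"] = table["interval_mass_g"].round(4)
    table.to_csv(tsv, sep="\t", index=False)

    balance = report.balance.copy()
    balance["balance_total_pct"] = balance["balance_total_pct"].round(1)
    balance.to_csv(bal, sep="\t", index=False)

    js.write_text(report.to_json() + "\n")
    return {"table": tsv, "balance": bal, "json": js}
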