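"""Readers and writers for spectrum CSVs, cohort manifests and provenance.

Spectrum CSV dialect (fixed to avoid locale drift): comma-separated,
dot decimal, UTF-8, header ``frequency_khz,resistance_ohm,reactance_ohm``,
with optional leading comment lines ``#key=value`` carrying recording
metadata (subject_id, muscle, side, gender, age).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .spectra import ImpedanceSpectrum, SpectrumMeta
from .simulate import SimulatedCohort

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_cohort",
    "read_manifest",
    "MANIFEST_COLUMNS",
]

_HEADER = ("frequency_khz", "resistance_ohm", "reactance_ohm")

MANIFEST_COLUMNS = (
    "subject_id",
    "gender",
    "age",
    "weight_kg",
    "height_m",
    "muscle",
    "side",
    "spectrum_file",
)


def read_spectrum(path) -> ImpedanceSpectrum:
    """Parse one spectrum CSV; rows are returned sorted by frequency.

    Raises :class:`ParseError` (with the line number) on a malformed
    header, a non-numeric cell, or a duplicated frequency.
    """
    path = Path(path)
    meta_kv: dict[str, str] = {}
    rows: list[tuple[float, float, float]] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, _, v = line[1:].partition("=")
                    meta_kv[k.strip()] = v.strip()
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if tuple(fields) != _HEADER:
                    raise ParseError(
                        f"expected header {','.join(_HEADER)!r}, got {line!r}", line=lineno
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise ParseError(f"expected 3 columns, got {len(fields)}", line=lineno)
            try:
                rows.append(tuple(float(f) for f in fields))
            except ValueError:
                raise ParseError(f"non-numeric cell in {line!r}", line=lineno) from None
    if not header_seen:
        raise ParseError("missing header", line=1)
    if not rows:
        raise ParseError("no data rows", line=1)
    arr = np.array(rows, dtype=float)
    freqs = arr[:, 0]
    uniq, counts = np.unique(freqs, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        # report the line of the *second* occurrence of the duplicate
        idx = np.flatnonzero(freqs == dup)[1]
        raise ParseError(f"duplicate frequency {dup:g} kHz", line=int(idx) + 2)
    order = np.argsort(freqs)
    arr = arr[order]
    age = meta_kv.get("age")
    meta = SpectrumMeta(
        subject_id=meta_kv.get("subject_id", ""),
        muscle=meta_kv.get("muscle", ""),
        side=meta_kv.get("side", "unspecified"),
        gender=meta_kv.get("gender", ""),
        age=float(age) if age not in (None, "") else None,
    )
    return ImpedanceSpectrum(
        frequencies=arr[:, 0], resistance=arr[:, 1], reactance=arr[:, 2], meta=meta
    )


def write_spectrum(spectrum: ImpedanceSpectrum, path) -> None:
    """Write a spectrum in the canonical CSV dialect (metadata as #key=value)."""
    path = Path(path)
    m = spectrum.meta
    with path.open("w", encoding="utf-8") as fh:
        for key, val in (
            ("subject_id", m.subject_id),
            ("muscle", m.muscle),
            ("side", m.side),
            ("gender", m.gender),
            ("age", "" if m.age is None else f"{m.age:g}"),
        ):
            if val:
                fh.write(f"#{key}={val}\n")
        fh.write(",".join(_HEADER) + "\n")
        for f, r, x in zip(spectrum.frequencies, spectrum.resistance, spectrum.reactance):
            fh.write(f"{float(f)!r},{float(r)!r},{float(x)!r}\n")


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest TSV and check its column set."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"manifest missing columns {sorted(missing)}")
    return df


def write_cohort(sim: SimulatedCohort, outdir) -> Path:
    """Write a simulated cohort: spectrum CSVs, manifest TSV, provenance JSON.

    Returns the manifest path.  The provenance file echoes the generator
    config, the calibration constants, and each subject's ground-truth
    Cole parameters so that recovery tests can use them as oracles.
    """
    outdir = Path(outdir)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth: dict[str, dict] = {}
    for subject in sim.subjects:
        rec = subject.record
        truth[rec.subject_id] = {
            f"{muscle}|{side}": asdict(params)
            for (muscle, side), params in subject.true_params.items()
        }
        for (muscle, side), spectrum in subject.spectra.items():
            fname = f"{rec.subject_id}_{muscle}_{side}.csv"
            write_spectrum(spectrum, spectra_dir / fname)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "gender": rec.gender,
                    "age": rec.age,
                    "weight_kg": round(rec.weight_kg, 1),
                    "height_m": round(rec.height_m, 3),
                    "muscle": muscle,
                    "side": side,
                    "spectrum_file": f"spectra/{fname}",
                }
            )
    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, sep="\t", index=False
    )
    provenance = {
        "config": asdict(sim.config),
        "calibration": {
            f"{muscle}|{gender}": asdict(cell)
            for (muscle, gender), cell in sim.calibration.items()
        },
        "true_parameters": truth,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return manifest_path
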