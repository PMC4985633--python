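"""Reading and writing the columnar text formats of the pipeline.

All scattering inputs are plain text: 2-3 column (Q, I[, sigma]) SANS
curves, 2 column (Q, S(Q)) diffractograms, and elastic scans in either
long format (T, Q2, I[, sigma]) or wide format (first column Q^2, one
intensity column per temperature named in the header).  Lines starting
with ``#`` are comments everywhere.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ElasticScan
from .guinier import ScatteringCurve
from .liquids import IntraMolecularPair, StructureFactor

__all__ = [
    "read_columns",
    "read_curve",
    "read_structure_factor",
    "read_elastic_scan",
    "write_curve",
    "load_guinier_table",
    "load_hbond_distances",
    "load_ectoine_intramolecular",
]


def read_columns(path: str | Path, min_cols: int = 2) -> np.ndarray:
    """Whitespace- or comma-separated numeric columns; '#' comments.

    Returns an (n_rows, n_cols) array; raises with the offending line
    number on non-numeric rows or ragged column counts.
    """
    rows: list[list[float]] = []
    ncols = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric row {line!r}") from exc
        if ncols is None:
            ncols = len(vals)
        elif len(vals) != ncols:
            raise ValueError(f"{path}:{ln}: expected {ncols} columns, got {len(vals)}")
        rows.append(vals)
    if not rows or ncols is None or ncols < min_cols:
        raise ValueError(f"{path}: need at least {min_cols} numeric columns")
    return np.asarray(rows, dtype=float)


def read_curve(path: str | Path, **metadata) -> ScatteringCurve:
    """SANS curve from (Q, I[, sigma]) text; sigma column optional."""
    data = read_columns(path, min_cols=2)
    if np.any(np.diff(data[:, 0]) <= 0):
        raise ValueError(f"{path}: Q must be strictly increasing")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(q=data[:, 0], i=data[:, 1], sigma=sigma, **metadata)


def read_structure_factor(path: str | Path, rho0: float, label: str = "") -> StructureFactor:
    """Structure factor from (Q, S(Q)) text; rho0 supplied by the caller."""
    data = read_columns(path, min_cols=2)
    return StructureFactor(q=data[:, 0], s=data[:, 1], rho0=rho0, label=label)


def read_elastic_scan(path: str | Path, label: str = "") -> ElasticScan:
    """Elastic scan from long (T, Q2, I[, sigma]) or wide text.

    Wide format: a header comment ``# q2 T1 T2 ...`` naming the
    temperatures, then rows of Q^2 followed by one intensity per
    temperature.
    """
    path = Path(path)
    temps_header: list[float] | None = None
    for raw in path.read_text().splitlines():
        if raw.lstrip().startswith("#"):
            parts = raw.lstrip("# \t").replace(",", " ").split()
            if len(parts) >= 3 and parts[0].lower() in ("q2", "qsq", "q^2"):
                temps_header = [float(p) for p in parts[1:]]
        else:
            break
    data = read_columns(path, min_cols=2)
    if temps_header is not None:
        if data.shape[1] != 1 + len(temps_header):
            raise ValueError(
                f"{path}: wide scan needs {1 + len(temps_header)} columns "
                f"(q2 + one per temperature)"
            )
        q2 = data[:, 0]
        t = np.repeat(temps_header, len(q2))
        q2_full = np.tile(q2, len(temps_header))
        i = data[:, 1:].T.ravel()
        return ElasticScan(temperature=t, q2=q2_full, intensity=i, label=label)
    if data.shape[1] < 3:
        raise ValueError(f"{path}: long-format scan needs (T, Q2, I[, sigma])")
    sigma = data[:, 3] if data.shape[1] >= 4 else None
    return ElasticScan(
        temperature=data[:, 0], q2=data[:, 1], intensity=data[:, 2],
        sigma=sigma, label=label,
    )


def write_curve(curve: ScatteringCurve, path: str | Path, header: str = "") -> None:
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.append("# Q(1/A)  I(1/cm)" + ("  sigma(1/cm)" if curve.sigma is not None else ""))
    for k in range(len(curve.q)):
        row = f"{curve.q[k]:.8g} {curve.i[k]:.8g}"
        if curve.sigma is not None:
            row += f" {curve.sigma[k]:.8g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return resources.files("neutroshell.data").joinpath(name)


def load_guinier_table() -> pd.DataFrame:
    """Published contrast-variation Guinier table (8 conditions)."""
    with resources.as_file(_data_path("guinier_conditions.csv")) as p:
        return pd.read_csv(p, comment="#")


def load_hbond_distances() -> pd.DataFrame:
    """Published water H-bond distances, bulk vs ectoine solution."""
    with resources.as_file(_data_path("hbond_distances.csv")) as p:
        return pd.read_csv(p, comment="#").set_index("sample")


def load_ectoine_intramolecular() -> list[IntraMolecularPair]:
    """Idealized (synthetic stand-in) ectoine intramolecular pair list."""
    with resources.as_file(_data_path("ectoine_intramolecular.csv")) as p:
        df = pd.read_csv(p, comment="#")
    return [
        IntraMolecularPair(
            label=row["label"], distance=row["distance_A"],
            weight=row["weight"], gamma=row["gamma_A2"],
        )
        for _, row in df.iterrows()
    ]
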