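"""Bit-stable tabular outputs and the run manifest.

Numbers are serialized with fixed formatting (deviances 1 dp, pseudo-R^2
2 dp, rho 3 dp) so repeated runs diff cleanly.  The report guard re-derives
the pseudo-R^2 column from the deviance columns and refuses to print an
inconsistent row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .mva import MVAModel


def fmt_deviance(x: float) -> str:
    return f"{x:.1f}"


def fmt_r2(x: float) -> str:
    return f"{x:.2f}"


def fmt_rho(x: float) -> str:
    return f"{x:.3f}"


def mva_report(models: list[MVAModel], group: str = "all") -> pd.DataFrame:
    """One row per fitted multivariable model, Table-style.

    Raises if a model's pseudo-R^2 is not reproducible from its deviances
    (|1 - res/null - R^2| > 5e-3), which guards the deviance-ratio
    convention end to end.
    """
    rows = []
    for m in models:
        if m.variables and m.null_deviance:
            derived = 1.0 - m.resid_deviance / m.null_deviance
            if abs(derived - m.pseudo_r2) > 5e-3:
                raise ValueError(
                    f"{m.dependent}: pseudo-R^2 {m.pseudo_r2} inconsistent with "
                    f"deviances {m.resid_deviance}/{m.null_deviance}")
        annotated = " ".join(f"{v} ({m.signs[v]})" if v in m.signs else v
                             for v in m.variables) or "no variables selected"
        rows.append({
            "dependent": m.dependent, "group": group, "n": m.n,
            "residual_deviance": fmt_deviance(m.resid_deviance) if m.variables else "",
            "null_deviance": fmt_deviance(m.null_deviance) if m.variables else "",
            "pseudo_r2": fmt_r2(m.pseudo_r2) if m.variables else "",
            "independent_variables": annotated,
        })
    return pd.DataFrame(rows)


def correlation_report(screen: pd.DataFrame) -> pd.DataFrame:
    """Long-format correlation table with fixed rho/R^2 formatting."""
    out = screen.copy()
    for col, f in (("rho", fmt_rho), ("pseudo_r2", fmt_rho)):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f(v))
    return out


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, *, seed: int, stages: list[str],
                   outputs: list[str | Path], row_counts: dict[str, int]) -> dict:
    """Machine-readable run manifest: inputs, seeds, digests, row counts."""
    import ocumarker
    manifest = {
        "version": getattr(ocumarker, "__version__", "0"),
        "seed": seed,
        "stages": stages,
        "row_counts": row_counts,
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
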