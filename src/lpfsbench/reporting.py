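"""Rendering of results into TSV/Markdown tables and SVG figures.

Rendering is a pure function of the results bundle: numeric display is fixed
at 2 decimals (full precision stays in the JSON bundle), column order is
fixed, and re-rendering the same bundle yields identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .benchmarks import SeverityBenchmarks, test_characteristic_curve
from .core import ValidationError, log
from .irt import FitResult, test_information


@dataclass(frozen=True)
class ReportBundle:
    """References to stage outputs plus provenance for reproducibility."""

    provenance: dict
    item_table: pd.DataFrame | None = None
    loading_table: pd.DataFrame | None = None
    eigenvalue_table: pd.DataFrame | None = None
    benchmark_table: pd.DataFrame | None = None
    classification_counts: dict | None = None
    validation_continuous: pd.DataFrame | None = None
    validation_categorical: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    return out


def render_tables(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write every available table as TSV plus one Markdown summary report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    named = {
        "item_parameters": bundle.item_table,
        "factor_loadings": bundle.loading_table,
        "eigenvalues": bundle.eigenvalue_table,
        "benchmarks": bundle.benchmark_table,
        "validation_continuous": bundle.validation_continuous,
        "validation_categorical": bundle.validation_categorical,
    }
    md_parts = ["# LPFS-BF 2.0 severity benchmark report", ""]
    md_parts.append("## Provenance")
    md_parts.append("```json")
    md_parts.append(json.dumps(bundle.provenance, indent=2, sort_keys=True, default=str))
    md_parts.append("```")
    for name, df in named.items():
        if df is None:
            log.warning("report section %r missing from bundle; skipped", name)
            continue
        path = out_dir / f"{name}.tsv"
        _fmt(df).to_csv(path, sep="\t", index=False)
        written.append(path)
        md_parts += ["", f"## {name.replace('_', ' ')}", ""]
        md_parts.append(_fmt(df).to_markdown(index=False))
    if bundle.classification_counts is not None:
        md_parts += ["", "## classification counts", ""]
        for label, count in bundle.classification_counts.items():
            md_parts.append(f"- {label}: {count}")
    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(md_parts) + "\n")
    written.append(md_path)
    return written


def render_curves(
    fit_items: Sequence,
    benchmarks: SeverityBenchmarks,
    out_dir: str | Path,
    theta_range: tuple[float, float] = (-6.0, 6.0),
) -> list[Path]:
    """Test information curve and score characteristic curve (SVG).

    The score characteristic curve panel annotates the four suggested
    cut-offs at their latent anchors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    theta = np.linspace(*theta_range, 601)
    info = test_information(list(fit_items), theta)
    tcc = test_characteristic_curve(list(fit_items), theta)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(theta, info, color="black")
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("Test information")
    ax.set_title("Test information curve")
    info_path = out_dir / "test_information.svg"
    fig.savefig(info_path, format="svg", metadata={"Date": None})
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(theta, tcc, color="black")
    for m, cont, cut, label in zip(
        benchmarks.multipliers, benchmarks.continuous, benchmarks.cutoffs, benchmarks.labels
    ):
        ax.axhline(cut, color="grey", linestyle=":", linewidth=0.8)
        ax.axvline(m, color="grey", linestyle=":", linewidth=0.8)
        ax.annotate(
            f"{label}: {cut} ({cont:.2f})", xy=(m, cut),
            xytext=(m - 5.5, cut + 0.4), fontsize=7,
        )
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("Expected total score")
    ax.set_ylim(12, 48)
    ax.set_title("Scale characteristic curve")
    tcc_path = out_dir / "scale_characteristic.svg"
    fig.savefig(tcc_path, format="svg", metadata={"Date": None})
    plt.close(fig)
    return [info_path, tcc_path]


def curve_hashes(fit_items: Sequence, theta_range=(-6.0, 6.0)) -> dict:
    """Stable hashes of the rendered data arrays (not raster bytes)."""
    import hashlib

    theta = np.linspace(*theta_range, 601)
    info = test_information(list(fit_items), theta)
    return {
        "information": hashlib.sha256(np.round(info, 10).tobytes()).hexdigest(),
    }
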