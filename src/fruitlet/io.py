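"""CSV/image I/O and end-to-end orchestration of the phenotyping pipeline.

CSV dialect throughout: UTF-8, comma-separated, '.' decimal, mandatory
header row, missing values as empty fields.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import analysis, chlorophyll, spectra, trichomes
from .synthesis import Cohort, default_pca_spectra

logger = logging.getLogger("fruitlet")

__all__ = [
    "write_cohorts",
    "read_cohort_csv",
    "read_absorbance_csv",
    "quantify_spectra_table",
    "quantify_chlorophyll_table",
    "quantify_trichomes_table",
    "join_quantifications",
    "compute_anchors",
    "load_config",
]


def write_cohorts(out_dir, cohorts: Sequence[Cohort], with_images: bool = True) -> None:
    """Write cohort.csv, spectra.csv, absorbance.csv, truth.csv and images/.

    cohort.csv is the field sheet (identity, weights, water content);
    truth.csv additionally carries the generator's ground truths (trichome
    coverages, chlorophyll, band-ratio indices) for validation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = pd.concat([c.records for c in cohorts], ignore_index=True)
    field_cols = ["fruit_id", "cultivar", "dafb", "fresh_g", "dry_g", "water_pct"]
    records[field_cols].to_csv(out / "cohort.csv", index=False)
    records.to_csv(out / "truth.csv", index=False)
    all_spectra = [s for c in cohorts for s in c.spectra]
    spectra.write_spectra_csv(out / "spectra.csv", all_spectra)
    pd.concat([c.absorbance for c in cohorts], ignore_index=True).to_csv(
        out / "absorbance.csv", index=False
    )
    if with_images and any(c.micrographs for c in cohorts):
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for c in cohorts:
            for fid, img in c.micrographs.items():
                trichomes.write_micrograph(img_dir / f"{fid}.png", img)
    logger.info("wrote %d fruit records to %s", len(records), out)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_absorbance_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"fruit_id", "abs_664_1", "abs_648_6", "abs_750_0"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def quantify_spectra_table(spectra_list: Sequence[spectra.Spectrum]) -> pd.DataFrame:
    """Per-fruit CCI and PWI from a list of spectra."""
    return pd.DataFrame(
        {
            "fruit_id": [s.label for s in spectra_list],
            "cci": [spectra.compute_cci(s) for s in spectra_list],
            "pwi": [spectra.compute_pwi(s) for s in spectra_list],
        }
    )


def quantify_chlorophyll_table(absorbance: pd.DataFrame,
                               mass_normalize: bool = False) -> pd.DataFrame:
    """Chlorophyll a/b/total (and content when dry mass is present) per fruit."""
    rows = []
    for _, row in absorbance.iterrows():
        t = chlorophyll.AbsorbanceTriplet(
            abs_664_1=row["abs_664_1"], abs_648_6=row["abs_648_6"],
            abs_750_0=row["abs_750_0"],
        )
        dry = row.get("dry_mass_g")
        res = chlorophyll.quantify(t, dry_mass_g=dry, mass_normalize=mass_normalize)
        rows.append(
            {
                "fruit_id": row["fruit_id"],
                "chl_a": res.chl_a,
                "chl_b": res.chl_b,
                "chl_total": res.chl_total,
                "content_total_ug": res.content_total_ug,
            }
        )
    return pd.DataFrame(rows)


def quantify_trichomes_table(micrographs: Mapping[str, trichomes.Micrograph],
                             threshold: int | str = trichomes.DEFAULT_THRESHOLD,
                             invert: bool = False) -> pd.DataFrame:
    """Long-format coverage table: fruit_id, position, coverage_pct, ..."""
    rows = []
    for fid, img in micrographs.items():
        result = trichomes.quantify(img, threshold=threshold, invert=invert)
        for position, pct in zip(trichomes.ROI_POSITIONS, result.as_tuple()):
            rows.append(
                {
                    "fruit_id": fid,
                    "position": position,
                    "coverage_pct": pct,
                    "threshold": threshold,
                    "mm_per_pixel": img.mm_per_pixel,
                }
            )
    return pd.DataFrame(rows)


def join_quantifications(cohort: pd.DataFrame, *tables: pd.DataFrame) -> pd.DataFrame:
    """Left-join quantification tables onto the cohort sheet by fruit_id.

    Fruit missing from a table are kept with empty fields and logged.
    """
    out = cohort.copy()
    for table in tables:
        if table.empty:
            continue
        if "position" in table.columns:  # pivot long trichome table to wide
            table = table.pivot_table(
                index="fruit_id", columns="position", values="coverage_pct"
            ).rename(columns=lambda p: f"trichome_{p}_pct").reset_index()
        missing = set(out["fruit_id"]) - set(table["fruit_id"])
        if missing:
            logger.warning(
                "%d fruit missing from a quantification table (e.g. %s)",
                len(missing), sorted(missing)[0],
            )
        out = out.merge(table, on="fruit_id", how="left")
    return out


def compute_anchors(cohorts: Sequence[Cohort]) -> dict[str, float]:
    """Recompute the generator's calibration anchors from generated cohorts.

    Returns the dry-matter slopes per cultivar, the grand mean water content,
    the quadratic vertices of CCI (Fuji) and PWI (Honeycrisp) vs fresh
    weight, the Fuji chlorophyll-content vs weight Pearson r, and the percent
    variance on the first principal component of the combined spectra.
    """
    from scipy.stats import pearsonr

    records = pd.concat([c.records for c in cohorts], ignore_index=True)
    fuji = records[records["cultivar"] == "Fuji"]
    hc = records[records["cultivar"] == "Honeycrisp"]
    anchors: dict[str, float] = {}
    anchors["fuji_n"] = int(len(fuji))
    anchors["honeycrisp_n"] = int(len(hc))
    anchors["fuji_dry_slope"] = analysis.fit_linear(fuji["fresh_g"], fuji["dry_g"]).slope
    anchors["honeycrisp_dry_slope"] = analysis.fit_linear(hc["fresh_g"], hc["dry_g"]).slope
    anchors["mean_water_pct"] = float(records["water_pct"].mean())
    anchors["fuji_cci_vertex_g"] = analysis.fit_poly2(
        fuji["fresh_g"], fuji["cci"]
    ).vertex_x
    anchors["honeycrisp_pwi_vertex_g"] = analysis.fit_poly2(
        hc["fresh_g"], hc["pwi"]
    ).vertex_x
    anchors["fuji_chl_content_weight_r"] = float(
        pearsonr(fuji["chl_content_ug"], fuji["fresh_g"]).statistic
    )
    pca_input = default_pca_spectra(cohorts)
    anchors["pca_n"] = int(len(pca_input))
    pca = analysis.pca_spectra(pca_input, n_components=2)
    anchors["pc1_explained_pct"] = float(pca.explained_pct[0])
    return anchors


def load_config(path) -> dict:
    """Load a YAML (or JSON; YAML is a superset) pipeline configuration."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return cfg
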