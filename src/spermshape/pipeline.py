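"""End-to-end orchestration: inputs -> EFD -> filter -> PCA -> report.

Stages: load contours (chain-code files, contour CSV, or grayscale
images), estimate and normalize EFDs, run the two-pass abnormality
filter, measure head indicators, and—when at least two labeled groups
are present—compare groups (means, SDs, CVs, percent differences
against a declared reference group, classic tests, and Steel–Dwass for
three or more groups).  All tabular outputs are written as CSV/JSON
into the output directory together with the serialized configuration,
so a run is reproducible and each stage re-runnable from intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chaincode, measure, pca, segmentation
from .efd import (DEFAULT_N_HARMONICS, efd_estimate, efd_normalize,
                  flatten_coeffs)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_contours", "run_pipeline", "compare_groups",
           "save_shape_panels", "save_biplot", "save_score_scatter"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialized for provenance)."""

    input_path: str
    input_format: str = "auto"            # chc | csv | image | auto
    out_dir: str = "spermshape_out"
    n_harmonics: int = DEFAULT_N_HARMONICS
    abnormal_threshold: float = pca.DEFAULT_ABNORMAL_THRESHOLD
    min_area: float = segmentation.DEFAULT_MIN_AREA
    labels_path: str | None = None
    reference_group: str | None = None
    seed: int = 0
    um_per_px: float | None = None
    measures: tuple = ("aspect_ratio",)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        img = tifffile.imread(path)
    else:
        from PIL import Image

        img = np.asarray(Image.open(path).convert("L"))
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.uint8)


def load_contours(config: RunConfig) -> dict[str, np.ndarray]:
    """Load specimen contours according to the configured input format."""
    path = Path(config.input_path)
    fmt = config.input_format
    if fmt == "auto":
        if path.is_dir():
            fmt = "image"
        elif path.suffix.lower() == ".chc":
            fmt = "chc"
        elif path.suffix.lower() == ".csv":
            fmt = "csv"
        else:
            fmt = "image"
    if fmt == "chc":
        chains = chaincode.parse_chc(path)
        return {c.specimen_id: chaincode.chain_to_contour(c) for c in chains}
    if fmt == "csv":
        return chaincode.read_contour_csv(path)
    if fmt == "image":
        files = sorted(path.glob("*.png")) + sorted(path.glob("*.tif")) \
            + sorted(path.glob("*.tiff")) if path.is_dir() else [path]
        if not files:
            raise ValueError(f"no image files found under {path}")
        contours: dict[str, np.ndarray] = {}
        for f in files:
            img = _read_image(f)
            _, mask = segmentation.otsu_threshold(img)
            chains = segmentation.extract_contours(mask, config.min_area,
                                                   id_prefix=f"{f.stem}_")
            for c in chains:
                contours[c.specimen_id] = chaincode.chain_to_contour(c)
        return contours
    raise ValueError(f"unknown input format {config.input_format!r}")


def _load_labels(config: RunConfig, ids: list[str]) -> pd.Series | None:
    if config.labels_path is None:
        return None
    df = pd.read_csv(config.labels_path)
    if not {"specimen_id", "group_label"}.issubset(df.columns):
        raise ValueError("label map CSV needs columns specimen_id, group_label")
    labels = df.set_index("specimen_id")["group_label"]
    orphans = [sid for sid in ids if sid not in labels.index]
    if orphans:
        raise ValueError(f"specimens without group label: {orphans[:10]}"
                         + ("..." if len(orphans) > 10 else ""))
    return labels.reindex(ids)


def run_pipeline(config: RunConfig,
                 contours: dict[str, np.ndarray] | None = None) -> dict:
    """Execute every stage and write the report to ``config.out_dir``.

    ``contours`` may be supplied directly (e.g. from the synthetic
    generator), bypassing the input-loading stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    if contours is None:
        contours = load_contours(config)
    ids = list(contours.keys())
    logger.info("stage load: %d specimens in", len(ids))
    if len(ids) < 3:
        raise ValueError(f"pipeline needs >= 3 specimens, got {len(ids)}")

    coeffs = {}
    for sid, contour in contours.items():
        coeffs[sid] = efd_normalize(
            efd_estimate(contour, config.n_harmonics, specimen_id=sid))
    X = np.array([flatten_coeffs(coeffs[sid]) for sid in ids])
    names = pca.coefficient_names(X.shape[1])
    coef_df = pd.DataFrame(X, index=pd.Index(ids, name="specimen_id"),
                           columns=names)
    coef_df.insert(0, "phase_rad", [coeffs[s].phase_rad for s in ids])
    coef_df.insert(0, "rotation_rad", [coeffs[s].rotation_rad for s in ids])
    coef_df.insert(0, "scale_px", [coeffs[s].scale_px for s in ids])
    coef_df.insert(0, "N", config.n_harmonics)
    coef_df.to_csv(out / "coefficients.csv")
    logger.info("stage efd: %d x %d coefficient matrix", *X.shape)

    filt = pca.filter_abnormal(X, ids, config.abnormal_threshold)
    filt.pass1_model.to_json(out / "pca_pass1.json")
    filt.pass2_model.to_json(out / "pca_pass2.json")
    filt.pass1_scores.to_csv(out / "scores_pass1.csv")
    filt.pass2_scores.to_csv(out / "scores_pass2.csv")
    (out / "abnormal_ids.txt").write_text(
        "".join(f"{sid}\n" for sid in filt.abnormal_ids))
    logger.info("stage filter: %d in, %d abnormal out",
                len(ids), len(filt.abnormal_ids))

    rows = [measure.measure_head(sid, contours[sid], coeffs[sid])
            for sid in filt.normal_ids]
    mtable = measure.measurements_table(rows)
    if config.um_per_px:
        for col in ("major_px", "minor_px", "ap_length_px"):
            mtable[col.replace("_px", "_um")] = mtable[col] * config.um_per_px
        mtable["area_um2"] = mtable["area_px2"] * config.um_per_px**2
    mtable.to_csv(out / "measurements.csv")
    logger.info("stage measure: %d specimens measured", len(rows))

    loadings = pca.factor_loadings(filt.pass2_model, filt.normal_matrix)
    loadings.to_csv(out / "loadings_pass2.csv")

    report = {
        "n_specimens": len(ids),
        "n_abnormal": len(filt.abnormal_ids),
        "abnormal_ids": filt.abnormal_ids,
        "contribution_rates": filt.pass2_model.contribution_rates[:5].tolist(),
        "out_dir": str(out),
    }

    labels = _load_labels(config, filt.normal_ids)
    if labels is not None and labels.nunique() >= 2:
        mtable2 = mtable.join(labels)
        stats_report = compare_groups(mtable2, config.reference_group,
                                      measures=list(config.measures))
        stats_report["summary"].to_csv(out / "group_summary.csv")
        stats_report["tests"].to_csv(out / "group_tests.csv", index=False)
        with open(out / "group_stats.json", "w") as fh:
            json.dump({k: v for k, v in stats_report.items()
                       if k not in {"summary", "tests"}}, fh, indent=2)
        report["group_stats"] = stats_report
        logger.info("stage stats: %d groups compared", labels.nunique())
    else:
        logger.info("stage stats: skipped (fewer than 2 labeled groups)")
        report["group_stats"] = None
    return report


def compare_groups(measurements: pd.DataFrame,
                   reference_group: str | None,
                   measures: list[str] | None = None) -> dict:
    """Group summaries, percent differences vs the reference, and tests.

    ``measurements`` must carry a ``group_label`` column.  The reference
    group for percent differences must be named explicitly (its mean is
    the denominator; positive difference = the other group is smaller).
    """
    if "group_label" not in measurements.columns:
        raise ValueError("measurements table needs a group_label column")
    measures = measures or ["aspect_ratio"]
    groups = list(dict.fromkeys(measurements["group_label"]))
    if len(groups) < 2:
        raise ValueError("compare_groups needs >= 2 groups")
    if reference_group is None:
        raise ValueError("reference_group must be named explicitly "
                         "(percent-difference signs depend on it)")
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not among "
                         f"{groups}")

    from .stats import classic_tests, percent_difference, steel_dwass, \
        steel_dwass_table

    summary_rows, test_rows = [], []
    extra: dict = {"reference_group": reference_group}
    for m in measures:
        by = {g: measurements.loc[measurements["group_label"] == g, m]
              .to_numpy() for g in groups}
        ref = by[reference_group]
        for g in groups:
            summary_rows.append({
                "measure": m, "group": g, "n": by[g].size,
                "mean": by[g].mean(), "sd": by[g].std(ddof=1),
                "cv_percent": measure.coefficient_of_variation(by[g]),
                "percent_difference_vs_reference":
                    percent_difference(ref.mean(), by[g].mean()),
            })
            if 3 <= by[g].size <= 5000:
                r = classic_tests(by[g], kind="shapiro", groups=(g,))
                test_rows.append({"measure": m, **_row(r)})
        for g in groups:
            if g == reference_group:
                continue
            pair = (reference_group, g)
            for kind in ("t_two", "f_var", "ks_two"):
                r = classic_tests(ref, by[g], kind=kind, groups=pair)
                test_rows.append({"measure": m, **_row(r)})
        if len(groups) >= 3:
            sd = steel_dwass(by)
            extra.setdefault("steel_dwass", {})[m] = \
                steel_dwass_table(sd).to_dict(orient="records")
            for r in sd:
                test_rows.append({"measure": m, **_row(r)})
    return {"summary": pd.DataFrame(summary_rows),
            "tests": pd.DataFrame(test_rows), **extra}


def _row(r) -> dict:
    return {"test": r.test_name, "groups": "|".join(map(str, r.groups)),
            "statistic": r.statistic, "p_value": r.p_value,
            "label": r.significance_label}


# ---------------------------------------------------------------------------
# optional SVG shape panels

def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def save_shape_panels(model: pca.PCAModel, path, pcs=(1, 2, 3),
                      k_values=(-2.0, 0.0, 2.0)) -> None:
    """Mean and +-2 SD contour reconstructions per PC, one row each."""
    plt = _pyplot()
    fig, axes = plt.subplots(len(pcs), len(k_values),
                             figsize=(3 * len(k_values), 3 * len(pcs)),
                             squeeze=False)
    for i, pc in enumerate(pcs):
        for j, k in enumerate(k_values):
            contour = pca.reconstruct_along_pc(model, pc, k)
            ax = axes[i][j]
            closed = np.vstack([contour, contour[:1]])
            ax.plot(closed[:, 0], closed[:, 1], lw=1.2)
            ax.set_aspect("equal")
            ax.set_axis_off()
            ax.set_title(f"PC{pc}, {k:+.0f} SD", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_biplot(loadings: pd.DataFrame, path,
                display_threshold: float = 0.1) -> None:
    """PC1-PC2 loading arrows longer than the display threshold."""
    plt = _pyplot()

    arrows = pca.biplot_arrow_lengths(loadings, display_threshold)
    fig, ax = plt.subplots(figsize=(5, 5))
    circ = plt.Circle((0, 0), 1.0, fill=False, ls="--", color="grey")
    ax.add_patch(circ)
    for name, row in loadings.iterrows():
        if not arrows.loc[name, "display"]:
            continue
        ax.annotate("", xy=(row["PC1"], row["PC2"]), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", lw=0.8))
        ax.annotate(name, xy=(row["PC1"], row["PC2"]), fontsize=7)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_xlabel("PC1 loading")
    ax.set_ylabel("PC2 loading")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_score_scatter(scores: pd.DataFrame, path,
                       labels: pd.Series | None = None) -> None:
    """PC1-PC2 score scatter, colored by group when labels are given."""
    plt = _pyplot()

    fig, ax = plt.subplots(figsize=(5, 5))
    if labels is None:
        ax.scatter(scores["PC1"], scores["PC2"], s=8)
    else:
        for g, sub in scores.groupby(labels):
            ax.scatter(sub["PC1"], sub["PC2"], s=8, label=str(g))
        ax.legend(fontsize=7)
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
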