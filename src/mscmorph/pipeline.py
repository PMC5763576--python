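"""End-to-end orchestration: simulate → segment → measure → stats → report.

A run is fully described by a :class:`RunConfig` (YAML-serializable,
lossless round trip) and a seed; identical config+seed reproduce
byte-identical numeric tables.  Each stage writes its artifacts under
the run's output directory and contributes structured counts to the
summary, so the accounting (objects detected, rejected per rule, cells
retained after trimming) is auditable for any dataset.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth as growth_mod
from . import imaging, markers, morphometry, stats, synthetic, trf

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SyntheticConfig", "TRFConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class SyntheticConfig:
    n_donors: int = 3
    cells_per_group: int = 400
    n_fields: int = 2
    cells_per_field: int = 10
    field_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65
    fraction_border: float = 0.1
    fraction_touching: float = 0.2
    fraction_binucleate: float = 0.1
    fraction_debris: float = 0.1
    noise_sd: float = 10.0


@dataclass
class TRFConfig:
    """Telomere model for the simulated lanes.

    Intercept/rate define the linear length-vs-PD trend the lanes are
    drawn from (length at p1 ≈ 8.2 kbp, shortening ≈ 36.1 bp/PD); the
    donor rate SD matches the cohort spread.
    """

    length_at_pd0_kbp: float = 8.897
    shortening_bp_per_pd: float = 36.1
    donor_rate_sd: float = 12.4
    smear_sd_kbp: float = 0.8
    replicates: int = 3
    window: tuple[float, float] = (3.0, 20.0)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    gating: imaging.GatingParams = field(default_factory=imaging.GatingParams)
    trim: stats.TrimSpec = field(default_factory=stats.TrimSpec)
    transforms: dict = field(default_factory=lambda: dict(stats.DEFAULT_TRANSFORMS))
    trf: TRFConfig = field(default_factory=TRFConfig)
    markers_n_groups: int = 12
    report_sections: dict = field(
        default_factory=lambda: {
            "imaging": True,
            "summaries": True,
            "ranking": True,
            "anova": True,
            "pairwise": True,
            "ks": True,
            "fold_change": True,
            "growth": True,
            "trf": True,
            "markers": True,
            "figures": True,
        }
    )

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["field_size"] = list(d["synthetic"]["field_size"])
        d["trf"]["window"] = list(d["trf"]["window"])
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, data):
            if data is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(data) - names
            if bad:
                raise ValueError(f"unknown keys for {klass.__name__}: {sorted(bad)}")
            return klass(**data)

        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir"),
            synthetic=build(SyntheticConfig, raw.get("synthetic")),
            gating=build(imaging.GatingParams, raw.get("gating")),
            trim=build(stats.TrimSpec, raw.get("trim")),
            transforms=dict(raw.get("transforms") or stats.DEFAULT_TRANSFORMS),
            trf=build(TRFConfig, raw.get("trf")),
            markers_n_groups=int(raw.get("markers_n_groups", 12)),
            report_sections=dict(
                raw.get("report_sections") or cls().report_sections
            ),
        )
        cfg.synthetic.field_size = tuple(cfg.synthetic.field_size)
        cfg.trf.window = tuple(cfg.trf.window)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every enabled stage; returns the summary report dict.

    Artifacts (CSV tables, figures, summary.json) are written under
    ``out_dir`` (or ``config.out_dir``).  A stage failure raises
    :class:`PipelineError` naming the stage; artifacts written by
    earlier stages are retained.
    """
    out = Path(out_dir or config.out_dir or "")
    if str(out) in ("", "."):
        raise ValueError("run_pipeline requires an output directory (config.out_dir)")
    out.mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    sections = config.report_sections
    seeds = _child_seeds(config.seed, 6)
    summary: dict = {"seed": config.seed, "stages": {}}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s: start", name)
                fn()
            except Exception as exc:  # noqa: BLE001 — re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return deco

    sc = config.synthetic
    models = synthetic.TABLE2_SIZE_MODELS

    # ---- simulate ------------------------------------------------------
    records = pd_table = None

    @stage("simulate")
    def _simulate():
        nonlocal records, pd_table
        records, pd_table = synthetic.generate_passage_dataset(
            models, sc.n_donors, sc.cells_per_group, seed=seeds[0]
        )
        _write_csv(records, out / "cells_simulated.csv")
        _write_csv(pd_table, out / "pd_table.csv")
        summary["stages"]["simulate"] = {
            "n_cells": int(len(records)),
            "n_groups": int(len(pd_table)),
        }

    # ---- segment + measure --------------------------------------------
    if sections.get("imaging", True):

        @stage("imaging")
        def _imaging():
            rng = np.random.default_rng(seeds[1])
            rows = []
            counts = {r: 0 for r in imaging.REJECTION_REASONS}
            n_objects = 0
            for i in range(sc.n_fields):
                spec = synthetic.FieldSpec(
                    field_size=sc.field_size,
                    pixel_size=sc.pixel_size,
                    n_cells=sc.cells_per_field,
                    fraction_border=sc.fraction_border,
                    fraction_touching=sc.fraction_touching,
                    fraction_binucleate=sc.fraction_binucleate,
                    fraction_debris=sc.fraction_debris,
                    noise_sd=sc.noise_sd,
                    seed=int(rng.integers(2**31)),
                )
                field_img, _truth = synthetic.generate_field(spec, models[0])
                objs, accepted = imaging.segment_field(field_img, config.gating)
                n_objects += len(objs)
                for obj in objs:
                    counts[obj.rejection_reason] += 1
                for obj in accepted:
                    rec = morphometry.measure_cell(
                        obj.pixel_mask,
                        sc.pixel_size,
                        cell_id=obj.object_id,
                        donor="demo",
                        passage=models[0].passage_label,
                    )
                    rows.append({"field": i, **rec.as_dict()})
            cells = pd.DataFrame(rows)
            _write_csv(cells, out / "cells_imaged.csv")
            summary["stages"]["imaging"] = {
                "n_fields": sc.n_fields,
                "n_objects": n_objects,
                "accepted": counts["none"],
                "rejected": {k: v for k, v in counts.items() if k != "none"},
            }

    # ---- statistics ----------------------------------------------------
    @stage("stats")
    def _stats():
        n_before = len(records)
        trimmed = {
            var: stats.trim_table(
                records,
                var,
                stats.TrimSpec(config.trim.lower_fraction, config.trim.upper_fraction, var),
            )
            for var in morphometry.DESCRIPTOR_COLUMNS
        }
        area = trimmed["area"]
        summaries = pd.concat(
            [
                stats.group_skewness(
                    trimmed[var],
                    var,
                    stats.TransformSpec(var, config.transforms.get(var, 0.0)),
                )
                for var in morphometry.DESCRIPTOR_COLUMNS
            ],
            ignore_index=True,
        )
        if sections.get("summaries", True):
            _write_csv(summaries, out / "group_summaries.csv")
        if sections.get("ranking", True):
            ranking = stats.rank_pd_models(summaries, pd_table)
            _write_csv(ranking, out / "pd_model_ranking.csv")
            summary["stages"]["ranking"] = {
                "best_variable": ranking.iloc[0]["variable"],
                "best_summary_kind": ranking.iloc[0]["summary_kind"],
                "best_r_squared": float(ranking.iloc[0]["r_squared"]),
            }
        anova_p = None
        if sections.get("anova", True):
            anova = stats.anova_two_way(
                area, "area", stats.TransformSpec("area", config.transforms.get("area", 0.0))
            )
            _write_csv(anova, out / "anova_area.csv")
            anova_p = float(
                anova.loc[anova["effect"] == "passage", "p_value"].iloc[0]
            )
        if sections.get("pairwise", True):
            pairwise = stats.pairwise_bonferroni(
                area,
                "area",
                "passage",
                stats.TransformSpec("area", config.transforms.get("area", 0.0)),
                anova_p=anova_p,
            )
            _write_csv(pairwise, out / "pairwise_passages.csv")
        if sections.get("ks", True):
            ks = stats.ks_between_passages(area, "area", models[0].passage_label)
            _write_csv(ks, out / "ks_vs_p1.csv")
        # Table-2-style passage means: trim within each donor×passage group
        # (outlier removal should strip per-sample artifacts, not compress
        # the between-group size contrast the fold table reports), then
        # average donor-group means with equal donor weight
        per_group = (
            records.groupby(["donor", "passage"], sort=False)["area"]
            .apply(
                lambda x: float(
                    np.mean(
                        stats.trim_outliers(
                            x.to_numpy(),
                            stats.TrimSpec(
                                config.trim.lower_fraction, config.trim.upper_fraction, "area"
                            ),
                        )
                    )
                )
            )
            .reset_index(name="mean_area")
        )
        group_means = per_group.groupby("passage", sort=False)["mean_area"].mean()
        folds = stats.fold_change_table(group_means, models[0].passage_label)
        if sections.get("fold_change", True):
            _write_csv(folds, out / "fold_change.csv")
        summary["stages"]["stats"] = {
            "cells_before_trim": n_before,
            "cells_after_trim_area": int(len(area)),
            "mean_area_by_passage": {
                k: float(v) for k, v in group_means.items()
            },
            "fold_change_by_passage": {
                row["group"]: float(row["fold_change"]) for _, row in folds.iterrows()
            },
        }
        if sections.get("figures", True):
            _area_histograms(area, out / "figures" / "area_distributions.png")

    # ---- growth kinetics ----------------------------------------------
    if sections.get("growth", True):

        @stage("growth")
        def _growth():
            rng = np.random.default_rng(seeds[2])
            curves = []
            for donor, sub in pd_table.groupby("donor"):
                recs = []
                prev = 0.0
                for pnum, (_, row) in enumerate(sub.iterrows(), start=1):
                    delta = max(row["pd"] - prev, 0.5)
                    prev = row["pd"]
                    days = max(delta / rng.normal(0.85, 0.05), 1.0)
                    recs.append(
                        growth_mod.PassageRecord(
                            donor=donor,
                            passage=pnum,
                            seeded_density=1000.0,
                            harvested_density=1000.0 * 2**delta,
                            days_in_culture=days,
                            confluency_at_harvest=0.8,
                        )
                    )
                curves.append(growth_mod.cumulative_pd(recs).to_frame())
            growth_df = pd.concat(curves, ignore_index=True)
            _write_csv(growth_df, out / "growth_curves.csv")
            summary["stages"]["growth"] = {
                "mean_pd_per_day": float(growth_df["pd_per_day"].mean()),
                "final_cumulative_pd_mean": float(
                    growth_df.groupby("donor")["cumulative_pd"].max().mean()
                ),
            }

    # ---- telomere TRF --------------------------------------------------
    if sections.get("trf", True):

        @stage("trf")
        def _trf():
            rng = np.random.default_rng(seeds[3])
            tc = config.trf
            ladder = synthetic.default_ladder()
            rows = []
            for donor, sub in pd_table.groupby("donor"):
                rate = float(np.clip(rng.normal(tc.shortening_bp_per_pd, tc.donor_rate_sd), 5.0, None))
                intercept = rng.normal(tc.length_at_pd0_kbp, 0.15)
                for _, row in sub.iterrows():
                    true_len = intercept - rate * row["pd"] / 1000.0
                    lane_means = []
                    for rep in range(tc.replicates):
                        spec = synthetic.TRFSimSpec(
                            fragment_lengths=(true_len,),
                            fragment_weights=(1.0,),
                            smear_sd=tc.smear_sd_kbp,
                            seed=int(rng.integers(2**31)),
                            noise_sd=0.002,
                        )
                        lane = synthetic.generate_trf_lane(
                            spec, ladder, lane_id=f"{donor}-{row['passage']}-r{rep}"
                        )
                        lane = trf.subtract_background(lane)
                        lane_means.append(trf.mean_trf(lane, ladder, tc.window).mean_trf)
                    rows.append(
                        {
                            "donor": donor,
                            "passage": row["passage"],
                            "pd": row["pd"],
                            "true_length_kbp": true_len,
                            "mean_trf": float(np.mean(lane_means)),
                        }
                    )
            trf_df = pd.DataFrame(rows)
            _write_csv(trf_df, out / "trf_results.csv")
            rate_mean, rate_sd, per_donor = trf.shortening_rate(trf_df)
            summary["stages"]["trf"] = {
                "mean_trf_p1_kbp": float(
                    trf_df.query("passage == 'p1'")["mean_trf"].mean()
                ),
                "shortening_bp_per_pd_mean": rate_mean,
                "shortening_bp_per_pd_sd": rate_sd,
                "n_donors": int(len(per_donor)),
            }

    # ---- markers -------------------------------------------------------
    if sections.get("markers", True):

        @stage("markers")
        def _markers():
            panel = synthetic.generate_marker_panel(
                synthetic.MarkerSimSpec(n_groups=config.markers_n_groups, seed=seeds[4])
            )
            _write_csv(panel, out / "marker_panel.csv")
            corr = markers.pearson_matrix(panel)
            corr.to_csv(out / "marker_correlation.csv", float_format="%.10g")
            pca = markers.pca_markers(panel)
            pca.loadings.to_csv(out / "pca_loadings.csv", float_format="%.10g")
            if sections.get("figures", True):
                markers.heatmap_export(corr, out / "figures" / "marker_heatmap.png")
                _biplot(pca, out / "figures" / "pca_biplot.png")
            summary["stages"]["markers"] = {
                "r_area_pd_per_day": float(corr.loc["mean_cell_area", "pd_per_day"]),
                "pc1_explained_variance": float(pca.explained_variance_ratio[0]),
                "pc1_area_loading": float(pca.loadings.loc["mean_cell_area", "PC1"]),
                "pc1_pd_per_day_loading": float(pca.loadings.loc["pd_per_day", "PC1"]),
            }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _area_histograms(area_table: pd.DataFrame, path: Path) -> None:
    """Per-passage area distributions, raw and log scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    passages = list(dict.fromkeys(area_table["passage"]))
    fig, axes = plt.subplots(2, len(passages), figsize=(3 * len(passages), 5), squeeze=False)
    for j, p in enumerate(passages):
        x = area_table.loc[area_table["passage"] == p, "area"].to_numpy()
        axes[0, j].hist(x, bins=40, density=True, color="#4878a8")
        axes[0, j].set_title(str(p))
        axes[1, j].hist(np.log(x), bins=40, density=True, color="#4878a8")
        axes[1, j].set_xlabel("log area")
    axes[0, 0].set_ylabel("area (μm²)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _biplot(pca: "markers.PCAResult", path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pca.scores["PC1"], pca.scores["PC2"], s=12, color="#666666")
    scale = float(np.abs(pca.scores[["PC1", "PC2"]].to_numpy()).max())
    for name, row in pca.loadings.iterrows():
        ax.annotate(
            name,
            (row["PC1"] * scale, row["PC2"] * scale),
            color="#c0392b",
            ha="center",
        )
        ax.plot([0, row["PC1"] * scale], [0, row["PC2"] * scale], color="#c0392b", lw=0.8)
    ax.set_xlabel(f"PC1 ({pca.explained_variance_ratio[0]:.0%})")
    ax.set_ylabel(f"PC2 ({pca.explained_variance_ratio[1]:.0%})")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
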