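"""Top-level orchestration: sessions in, structured report directory out.

Order of stages mirrors the analysis: unit deduplication → per unit-odour
response metrics and fractions → feature comparisons between genotypes →
similarity curves and ANOVAs → population distances → subsampled decoding
with chance tests and a genotype comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, responses, similarity
from .detection import dedup_units
from .responses import AnalysisWindows
from .stats import binomial_test_one_sided


@dataclass
class RunConfig:
    """Pipeline defaults; every stated analysis constant appears here once."""

    psth_bin: float = 0.05          # s, PSTH bin width
    z_bin: float = 0.1              # s, z-trace bin width
    baseline_window: tuple = (-2.5, -0.5)
    odour_window: tuple = (0.0, 0.5)
    z_thr: float = 1.96             # two-sided 95% normal critical value
    min_rate_hz: float = 0.5        # AON unit inclusion floor
    detection_factor: float = 7.5   # spike threshold multiple
    n_trials: int = 19
    pca_dim: int = 4
    decode_iters: int = 500
    size_step: int = 10
    classifier: str = "gaussian"
    knn_k: int = 5
    chance: float = 1.0 / 6.0
    seed: int = 0
    apply_dedup: bool = True

    def windows(self) -> AnalysisWindows:
        return AnalysisWindows(
            psth_bin=self.psth_bin,
            z_bin=self.z_bin,
            baseline_window=self.baseline_window,
            odour_window=self.odour_window,
            z_thr=self.z_thr,
        )


def _feature_comparisons(table: pd.DataFrame) -> list[dict]:
    out = []
    for label in ("excited", "inhibited"):
        sub = table[(table["label"] == label) & ~table["degenerate"]]
        for feature in ("peak_z", "peak_width", "time_to_peak"):
            groups = {
                g: sub.loc[sub["genotype"] == g, feature].dropna().to_numpy()
                for g in sorted(sub["genotype"].unique())
            }
            if len(groups) != 2 or any(v.size < 3 for v in groups.values()):
                continue
            a, b = groups.values()
            vals = np.abs(a) if feature == "peak_z" and label == "inhibited" else a
            valsb = np.abs(b) if feature == "peak_z" and label == "inhibited" else b
            try:
                res = responses.compare_feature_distributions(vals, valsb)
            except ValueError:
                continue
            out.append(dict(label=label, feature=feature, **res))
    return out


def run_pipeline(sessions_by_genotype: dict, config: RunConfig | None = None,
                 out_dir=None) -> dict:
    """Run all stages on {genotype: [RecordingSession, ...]} and summarize.

    Returns the machine-readable summary; when ``out_dir`` is given, tidy
    tables per stage, the summary JSON and a run log are written there.
    """
    config = config or RunConfig()
    windows = config.windows()
    log: list[str] = [f"config: {asdict(config)}"]

    tables, fractions, curves, decode_frames = [], {}, {}, []
    anovas: dict = {}
    pops = {}
    for genotype, sessions in sessions_by_genotype.items():
        sessions = dedup_units(sessions) if config.apply_dedup else list(sessions)
        log.append(f"{genotype}: {sum(len(s.units) for s in sessions)} units "
                   f"after dedup across {len(sessions)} session(s)")
        table = pd.concat(
            [responses.unit_odour_table(s, windows) for s in sessions],
            ignore_index=True,
        )
        tables.append(table)
        zlist = [
            z for s in sessions for z in responses.session_zresponses(s, windows)
        ]
        fractions[genotype] = responses.response_fractions(zlist)
        n_degenerate = sum(z.degenerate for z in zlist)
        log.append(f"{genotype}: {n_degenerate} degenerate (sigma=0) unit-odour pairs")
        pops[genotype] = decoding.build_pseudopopulation(
            sessions, n_trials=config.n_trials, window=config.odour_window
        )

    table = pd.concat(tables, ignore_index=True)
    # unit key must be globally unique across sessions/genotypes for the
    # repeated-measures matching
    rel_input = table.assign(unit_id=table["session_id"] + "/" + table["unit_id"])
    rel = similarity.relative_responses(
        rel_input[["unit_id", "odour_carbon", "response_strength", "genotype"]]
    )
    chain_curve = similarity.chain_distance_curve(rel)
    rank_curve = similarity.ranked_curve(rel, exclude_rank_1=True)
    if rel["genotype"].nunique() == 2:
        anovas["chain_distance"] = similarity.two_way_anova(
            rel[rel["chain_distance"] > 0], "relative_strength",
            "genotype", "chain_distance",
        )
        anovas["rank"] = similarity.two_way_anova(
            rel[rel["rank"] > 1], "relative_strength", "genotype", "rank",
            repeated_on="unit_id",
        )
    per_genotype_chain = {
        g: similarity.chain_distance_effect(rel[rel["genotype"] == g])
        for g in rel["genotype"].unique()
    }

    distance_tests = {}
    for genotype, pop in pops.items():
        summ = decoding.cross_odour_distances(pop)
        distance_tests[genotype] = {
            "degenerate": summ.degenerate,
            "omnibus_F": None if summ.omnibus is None else summ.omnibus.statistic,
            "omnibus_df": None if summ.omnibus is None else summ.omnibus.df,
            "omnibus_p": None if summ.omnibus is None else summ.omnibus.p,
        }
        sizes = np.arange(
            min(config.size_step, pop.n_units), pop.n_units + 1, config.size_step
        )
        curves[genotype] = decoding.decode_accuracy(
            pop, classifier=config.classifier, sizes=sizes,
            iters=config.decode_iters, pca_dim=config.pca_dim,
            seed=config.seed, k=config.knn_k,
        )
        decode_frames.append(curves[genotype].to_frame().assign(genotype=genotype))

    summary = {
        "fractions": fractions,
        "feature_comparisons": _feature_comparisons(table),
        "similarity_anovas": {
            k: {"effects": v.effects, "kind": v.kind} for k, v in anovas.items()
        },
        "chain_distance_effect_per_genotype": per_genotype_chain,
        "distance_tests": distance_tests,
        "decoding": {
            g: {
                "sizes": c.sizes.tolist(),
                "accuracy": c.accuracy.tolist(),
                "binom_p": c.binom_p.tolist(),
                "headline_p": float(c.binom_p[-1]),
            }
            for g, c in curves.items()
        },
    }
    if len(curves) == 2:
        (ga, ca), (gb, cb) = curves.items()
        common = np.intersect1d(ca.sizes, cb.sizes)
        if common.size:
            ia = np.isin(ca.sizes, common)
            ib = np.isin(cb.sizes, common)
            sub_a = decoding.DecodingCurve(ca.classifier, ca.sizes[ia], ca.outcomes[ia],
                                           ca.accuracy[ia], ca.chance, ca.binom_p[ia], ca.seed)
            sub_b = decoding.DecodingCurve(cb.classifier, cb.sizes[ib], cb.outcomes[ib],
                                           cb.accuracy[ib], cb.chance, cb.binom_p[ib], cb.seed)
            comp = decoding.compare_decoding_curves(sub_a, sub_b)
            summary["decoding_comparison"] = {
                "genotype_a": ga,
                "genotype_b": gb,
                "table": comp.to_dict(orient="records"),
            }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "unit_odour_responses.csv", index=False)
        rel.to_csv(out / "relative_responses.csv", index=False)
        chain_curve.to_csv(out / "chain_distance_curve.csv", index=False)
        rank_curve.to_csv(out / "ranked_curve.csv", index=False)
        if decode_frames:
            pd.concat(decode_frames, ignore_index=True).to_csv(
                out / "decoding_curves.csv", index=False
            )
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=_json_default))
        (out / "run.log").write_text("\n".join(log) + "\n")
    return summary


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)
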