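"""End-to-end experiment runner: simulate -> translate -> compare.

Reproduces the full analysis workflow on a synthetic cohort: generate (or
load) a paired Go/Nogo ERP dataset, run the conditional-GAN translation in
one or both directions under subject-level K-fold cross-validation, compare
generated and real signals with the cluster-based permutation test, and
aggregate significance into 50-ms epochs. Every stochastic stage draws a
named sub-seed from the global seed, so a rerun with the same configuration
is reproducible end to end; stage outputs are persisted as they complete.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .datasets import GO, NOGO, ERPDataset
from .simulate import Trial, make_fixture_cohort
from .stats import (
    ComponentWindows,
    PermutationConfig,
    aggregate_epochs,
    cluster_permutation,
    cluster_table,
    paired_cohens_d,
    rm_anova_2x2,
    window_mean,
)
from .translator import TrainConfig, generated_dataset, translate_cohort

_STAGE_CODES = {"simulate": 1, "translate": 2, "permutation": 3}


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, _STAGE_CODES[stage], index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    preset: str = "paper_like"
    n_subjects: int = 40
    directions: tuple = ("go2nogo",)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(k_folds=5, base_filters=8))
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    windows: ComponentWindows = field(default_factory=ComponentWindows)
    seed: int = 0
    out_dir: str | None = None
    dataset_path: str | None = None  # load instead of simulating


@dataclass
class RunReport:
    config: dict
    erp_stats: dict
    translations: dict
    cluster_counts: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "erp_stats": self.erp_stats,
                "translations": self.translations,
                "cluster_counts": self.cluster_counts,
                "provenance": self.provenance,
            },
            indent=1,
            default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def _erp_window_stats(dataset: ERPDataset, windows: ComponentWindows) -> dict:
    """Standard component quantification on whatever electrodes exist."""
    out = {}
    names = set(dataset.layout.names)
    specs = {
        "N2": (windows.n2, [windows.electrode_n2]),
        "P3_frontocentral": (windows.p3_frontocentral, [windows.electrode_p3_frontocentral]),
        "P3_parietal": (windows.p3_parietal, [windows.electrode_p3_parietal]),
    }
    for comp, (win, electrodes) in specs.items():
        if not set(electrodes) <= names:
            out[comp] = {"skipped": f"electrodes {electrodes} not in layout"}
            continue
        means = window_mean(dataset, win, electrodes)
        go, nogo = means[GO], means[NOGO]
        anova = rm_anova_2x2(go, go, nogo, nogo)  # degenerate B: F_A = paired t^2
        out[comp] = {
            "window_ms": list(win),
            "electrodes": electrodes,
            "mean_go": float(go.mean()),
            "mean_nogo": float(nogo.mean()),
            "F_condition": anova["A"].F,
            "p_condition": anova["A"].p,
            "eta_p2": anova["A"].eta_p2,
            "cohens_d": paired_cohens_d(nogo, go),
        }
    return out


def run_experiment(config: RunConfig) -> RunReport:
    """Execute the full workflow; see the module docstring."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if config.dataset_path:
        dataset = ERPDataset.load(config.dataset_path)
    else:
        dataset = make_fixture_cohort(
            config.preset, n_subjects=config.n_subjects,
            seed=stage_seed(config.seed, "simulate"),
        )
    if out_dir:
        dataset.save(out_dir / "dataset")

    erp_stats = _erp_window_stats(dataset, config.windows)

    translations = {}
    cluster_counts = {}
    for d_idx, direction in enumerate(config.directions):
        try:
            tr_cfg = TrainConfig(
                **{**asdict(config.train), "seed": stage_seed(config.seed, "translate", d_idx)}
            )
            report = translate_cohort(dataset, direction, tr_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'translate' failed for {direction}: {exc}") from exc
        gen_ds = generated_dataset(dataset, report)
        if out_dir:
            gen_ds.save(out_dir / f"generated_{direction}")
        perm_cfg = PermutationConfig(
            n_draws=config.permutation.n_draws,
            alpha=config.permutation.alpha,
            min_neighbor_channels=config.permutation.min_neighbor_channels,
            seed=stage_seed(config.seed, "permutation", d_idx),
        )
        result = cluster_permutation(dataset, gen_ds, perm_cfg, condition=report.target)
        agg = aggregate_epochs(result)
        translations[direction] = {
            "mean_r": report.mean_r,
            "per_channel_r": report.per_channel_r,
            "test_l1_normalized": report.test_l1_normalized,
            "cohort_l1_normalized": report.cohort_l1_normalized,
            "n_folds": len(report.folds),
        }
        cluster_counts[direction] = {
            "n_clusters": len(result.clusters),
            "n_significant_clusters": len(result.significant),
            "significant_epochs": agg.n_significant,
            "n_epochs": agg.n_epochs,
        }
        if out_dir:
            cluster_table(result).to_csv(out_dir / f"clusters_{direction}.csv", index=False)
            np.savetxt(out_dir / f"epoch_grid_{direction}.csv",
                       agg.grid.astype(int), fmt="%d", delimiter=",")

    report = RunReport(
        config={
            "preset": config.preset,
            "n_subjects": config.n_subjects,
            "directions": list(config.directions),
            "train": asdict(config.train),
            "permutation": asdict(config.permutation),
            "seed": config.seed,
        },
        erp_stats=erp_stats,
        translations=translations,
        cluster_counts=cluster_counts,
        provenance={"package": "erpgan", "version": __version__,
                    "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_CODES}},
    )
    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# behavior summary


def summarize_behavior(trials: list[Trial]) -> dict:
    """Descriptive behavioral statistics from a trial log.

    Go accuracy (%), mean RT over correct Go trials (ms) with SEM, and
    Nogo false-alarm rate (%). Rates whose denominator is empty are
    reported as None rather than 0.
    """
    if not trials:
        raise ValueError("empty trial log")
    go = [t for t in trials if t.condition == GO]
    nogo = [t for t in trials if t.condition == NOGO]
    out: dict = {"n_go": len(go), "n_nogo": len(nogo)}
    if go:
        correct = [t for t in go if t.correct]
        out["go_accuracy_pct"] = 100.0 * len(correct) / len(go)
        rts = np.array([t.rt_ms for t in correct if t.rt_ms is not None])
        out["go_mean_rt_ms"] = float(rts.mean()) if rts.size else None
        out["go_rt_sem_ms"] = float(rts.std(ddof=1) / np.sqrt(rts.size)) if rts.size > 1 else 0.0
    else:
        out["go_accuracy_pct"] = None
        out["go_mean_rt_ms"] = None
    out["nogo_false_alarm_pct"] = (
        100.0 * sum(1 for t in nogo if not t.correct) / len(nogo) if nogo else None
    )
    return out


# ---------------------------------------------------------------------------
# container validation


def validate_container(path) -> list[str]:
    """Schema and invariant checks of an on-disk dataset directory.

    Returns a list of human-readable violations; an empty list means the
    container is valid.
    """
    path = Path(path)
    violations = []
    sidecar_path = path / "dataset.json"
    if not sidecar_path.exists():
        return [f"missing sidecar {sidecar_path}"]
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except Exception as exc:
        return [f"unreadable sidecar: {exc}"]
    for key in ("subjects", "conditions", "fs", "t0_ms", "layout", "n_times"):
        if key not in sidecar:
            violations.append(f"sidecar missing field {key!r}")
    if violations:
        return violations
    if sidecar["fs"] <= 0:
        violations.append(f"fs must be positive, got {sidecar['fs']}")
    n_sub = len(sidecar["subjects"])
    n_ch = len(sidecar["layout"]["names"])
    for cond in sidecar["conditions"]:
        f = path / f"{cond}.npy"
        if not f.exists():
            violations.append(f"missing condition file {f.name}")
            continue
        try:
            arr = np.load(f)
        except Exception as exc:
            violations.append(f"unreadable condition file {f.name}: {exc}")
            continue
        if arr.ndim != 3:
            violations.append(f"{f.name}: expected 3 axes (subject, channel, time)")
            continue
        if arr.shape[0] != n_sub:
            violations.append(f"{f.name}: {arr.shape[0]} subjects, sidecar lists {n_sub}")
        if arr.shape[1] != n_ch:
            violations.append(f"{f.name}: {arr.shape[1]} channels, layout lists {n_ch}")
        if arr.shape[2] != sidecar["n_times"]:
            violations.append(
                f"{f.name}: {arr.shape[2]} samples, sidecar fs/n_times imply {sidecar['n_times']}"
            )
        if arr.size and not np.isfinite(arr).all():
            violations.append(f"{f.name}: non-finite values")
    return violations
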