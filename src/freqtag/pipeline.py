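"""End-to-end orchestration: simulate -> preprocess -> spectra -> inference.

`run_pipeline` executes the full analysis for a validated `RunConfig` and
returns a `RunReport`-shaped dictionary in which every number comes from a
module operation (no statistics are computed inline here). The root seed
fans out to per-stage substreams, so a fixed seed gives byte-identical JSON
summaries across runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel

from . import __version__
from .containers import EpochSet
from .inference import (
    classify_topographies,
    compare_conditions,
    correlate_behavior,
    empirical_null_test,
    fdr_correct,
    ftest_normalized_power,
    null_bin_pool,
    rayleigh_test,
)
from .io import write_behavior_tsv, write_json, write_spectra_tsv, write_tests_tsv
from .preprocessing import preprocess
from .simulate import (
    SimulationConfig,
    make_layout,
    simulate_subject_eeg,
    simulate_behavior,
    subject_traits,
)
from .spectral import (
    dft_coefficients,
    evoked_power,
    normalize_power,
    phase_coherence,
    induced_power,
    target_frequencies,
)
from .stimulus import StimulusSpec

__all__ = ["PreprocessingConfig", "AnalysisConfig", "RunConfig", "run_pipeline"]


class PreprocessingConfig(BaseModel, frozen=True, extra="forbid"):
    lowpass_hz: float = 25.0
    run_ica: bool = True
    n_pca: int = 80
    frontal_k: int = 14
    frontal_power_ratio: float = 10.0
    drop_first_sentence: bool = True
    exclude_outlier_trials: bool = True


class AnalysisConfig(BaseModel, frozen=True, extra="forbid"):
    #: wide enough that >= 50 finite normalized-power bins survive the
    #: harmonic exclusion and the +-0.5 Hz normalization edge
    null_pool_range: tuple[float, float] = (0.3, 5.5)
    null_guard_bins: int = 1
    fdr_q: float = 0.05
    classifier_ridge: float = 1e-3
    #: grand-average F dof convention; "per_subject" uses F(2, 28) per subject
    dof_mode: Literal["grand", "per_subject"] = "grand"
    half_width_hz: float = 0.5


class RunConfig(BaseModel, frozen=True, extra="forbid"):
    stimulus: StimulusSpec = StimulusSpec()
    simulation: SimulationConfig = SimulationConfig()
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    conditions: tuple[str, ...] = ("sentence", "control")
    seed: int = 0
    output_dir: str | None = None
    create_output_dir: bool = True
    write_artifacts: bool = True

    def config_hash(self) -> str:
        """Hash of the scientific configuration (I/O destination excluded)."""
        payload = self.model_dump(
            exclude={"output_dir", "create_output_dir", "write_artifacts"}
        )
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _subject_spectra(epochs: EpochSet, half_width: float):
    """Channel-averaged E/R/I plus per-channel E for topographies."""
    sc = dft_coefficients(epochs)
    E = evoked_power(sc)
    R = phase_coherence(sc)
    I = induced_power(sc)
    return sc, E, R, I


def _split_half_maps(epochs: EpochSet, bins: dict[str, int], resolution: float,
                     half_width: float) -> dict[str, dict[str, np.ndarray]]:
    """Per-channel normalized power at each target bin, per trial half."""
    half = epochs.n_trials // 2
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, sl in (("first_half", slice(0, half)),
                     ("second_half", slice(half, epochs.n_trials))):
        sub = EpochSet(
            data=epochs.data[sl], fs=epochs.fs,
            epoch_duration=epochs.epoch_duration,
            condition=epochs.condition, subject_id=epochs.subject_id,
            layout=epochs.layout,
        )
        sc = dft_coefficients(sub)
        En = normalize_power(evoked_power(sc), resolution, half_width)
        out[name] = {label: En[:, b] for label, b in bins.items()}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in fixed order; deterministic for a fixed seed."""
    out_dir = None
    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        if not out_dir.exists():
            if config.create_output_dir:
                out_dir.mkdir(parents=True)
            else:
                raise FileNotFoundError(f"output directory {out_dir} is missing")

    spec = config.stimulus
    sim = config.simulation.model_copy(update={"seed": config.seed})
    prep = config.preprocessing
    ana = config.analysis

    layout = make_layout(sim.n_channels)
    traits = subject_traits(sim)
    n_subjects = sim.n_subjects

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_subjects": n_subjects,
        },
        "conditions": {},
    }

    per_condition: dict[str, dict] = {}
    for condition in config.conditions:
        subj_E, subj_R, subj_I, subj_En = [], [], [], []
        maps_first: dict[str, list] = {}
        maps_second: dict[str, list] = {}
        rejection_reports = []
        targets = None
        freqs = None
        K = None

        for s in range(n_subjects):
            rec = simulate_subject_eeg(spec, sim, s, condition,
                                       layout=layout, traits=traits)
            epochs, rej = preprocess(
                rec, spec,
                lowpass_hz=prep.lowpass_hz,
                run_ica=prep.run_ica,
                n_pca=prep.n_pca,
                frontal_k=prep.frontal_k,
                ratio=prep.frontal_power_ratio,
                seed=config.seed + s,
                drop_first_sentence=prep.drop_first_sentence,
                exclude_outliers=prep.exclude_outlier_trials,
            )
            if rej is not None:
                rejection_reports.append(
                    {"subject": rec.subject_id, "removed": rej.removed}
                )
            sc, E, R, I = _subject_spectra(epochs, ana.half_width_hz)
            if targets is None:
                freqs = sc.freqs
                targets = target_frequencies(
                    freqs,
                    syllable_dur=spec.syllable_dur,
                    sentence_dur=spec.sentence_dur,
                )
                K = sc.K
            res = sc.resolution
            e_avg = E.mean(axis=0)
            subj_E.append(e_avg)
            subj_R.append(R.mean(axis=0))
            subj_I.append(I.mean(axis=0))
            subj_En.append(normalize_power(e_avg, res, ana.half_width_hz))
            halves = _split_half_maps(epochs, targets.bins, res, ana.half_width_hz)
            for label in targets.bins:
                maps_first.setdefault(label, []).append(halves["first_half"][label])
                maps_second.setdefault(label, []).append(halves["second_half"][label])

        subj_E = np.stack(subj_E)
        subj_R = np.stack(subj_R)
        subj_I = np.stack(subj_I)
        subj_En = np.stack(subj_En)
        resolution = float(freqs[1] - freqs[0])

        grand_E = subj_E.mean(axis=0)
        grand_R = subj_R.mean(axis=0)
        grand_I = subj_I.mean(axis=0)
        grand_En = normalize_power(grand_E, resolution, ana.half_width_hz)

        pool = null_bin_pool(
            freqs, targets.sentential_bin,
            freq_range=ana.null_pool_range, guard_bins=ana.null_guard_bins,
        )

        grand_tests = []
        for label, b in targets.bins.items():
            bps = int(np.floor(ana.half_width_hz / resolution - 1e-9))
            grand_tests.append(ftest_normalized_power(
                grand_En[b], n_subjects, bins_per_side=bps, target=label,
            ))
            grand_tests.append(empirical_null_test(
                grand_En[b], grand_En[pool], target=label,
                method="empirical_null_power",
            ))
            grand_tests.append(empirical_null_test(
                grand_R[b], grand_R[pool], target=label,
                method="empirical_null_coherence",
            ))

        # per-subject detection: empirical null pooled over subjects, then
        # BH-FDR across the 16 subjects within each (target, statistic)
        subject_tests = []
        detection = {}
        for stat_name, mat in (("power", subj_En), ("coherence", subj_R)):
            null_values = mat[:, pool]
            for label, b in targets.bins.items():
                results = [
                    empirical_null_test(
                        mat[s, b], null_values, target=label, scope="subject",
                        method=f"empirical_null_{stat_name}",
                    )
                    for s in range(n_subjects)
                ]
                qs, sig = fdr_correct([r.p for r in results], q=ana.fdr_q)
                for r, qv in zip(results, qs):
                    r.q = float(qv)
                subject_tests.extend(results)
                detection[f"{stat_name}_{label}"] = float(sig.mean() * 100.0)

        per_condition[condition] = {
            "freqs": freqs,
            "targets": targets,
            "K": K,
            "subj_E": subj_E, "subj_R": subj_R, "subj_En": subj_En,
            "grand_E": grand_E, "grand_R": grand_R, "grand_I": grand_I,
            "grand_En": grand_En,
            "grand_tests": grand_tests,
            "subject_tests": subject_tests,
            "maps_first": {k: np.stack(v) for k, v in maps_first.items()},
            "maps_second": {k: np.stack(v) for k, v in maps_second.items()},
        }

        report["conditions"][condition] = {
            "n_epochs_analyzed": K,
            "grand_tests": [_result_dict(r) for r in grand_tests],
            "subject_detection_pct": detection,
            "rejected_components": rejection_reports,
            "target_bins": dict(targets.bins),
            "grand_En_at_targets": {
                label: float(grand_En[b]) for label, b in targets.bins.items()
            },
        }

    # between-condition comparison on raw grand evoked power
    if {"sentence", "control"} <= set(config.conditions):
        sent = per_condition["sentence"]
        ctrl = per_condition["control"]
        comparisons = []
        for label, b in sent["targets"].bins.items():
            comparisons.append(compare_conditions(
                sent["grand_E"][b], ctrl["grand_E"][b], n_subjects, target=label,
            ))
        report["condition_comparison"] = [_result_dict(r) for r in comparisons]

    # split-half topography classification: sentential vs syllabic maps
    first_cond = config.conditions[0]
    pc = per_condition[first_cond]
    first = np.stack(
        [pc["maps_first"]["sentential"], pc["maps_first"]["syllabic"]], axis=1
    )
    second = np.stack(
        [pc["maps_second"]["sentential"], pc["maps_second"]["syllabic"]], axis=1
    )
    accuracy, clf_result = classify_topographies(
        first, second, ridge_scale=ana.classifier_ridge
    )
    report["topography_classification"] = {
        "classes": ["sentential", "syllabic"],
        "condition": first_cond,
        **_result_dict(clf_result),
    }

    # neural-behavior correlation at the sentential bin (sentence condition)
    if "sentence" in per_condition:
        pc = per_condition["sentence"]
        b = pc["targets"].bins["sentential"]
        neural = pc["subj_En"][:, b]
        scores = simulate_behavior(sim, traits["amp_sentential"])
        try:
            corr = correlate_behavior(neural, scores, target="sentential")
            report["behavior_correlation"] = _result_dict(corr)
        except ValueError as exc:  # tiny cohorts: too few pairs after exclusion
            report["behavior_correlation"] = {"skipped": str(exc)}
        report["behavior_scores"] = [float(x) for x in scores]

    if out_dir is not None and config.write_artifacts:
        _write_artifacts(out_dir, config, report, per_condition)
    return report


def _result_dict(r) -> dict:
    return {
        "method": r.method,
        "target": r.target,
        "scope": r.scope,
        "statistic": float(r.statistic),
        "dof": list(r.dof) if isinstance(r.dof, tuple) else r.dof,
        "p": float(r.p),
        "q": None if r.q is None else float(r.q),
        **({"extra": r.extra} if r.extra else {}),
    }


def _write_artifacts(out_dir: Path, config: RunConfig, report: dict,
                     per_condition: dict) -> None:
    write_json(out_dir / "summary.json", report)
    (out_dir / "config.json").write_text(
        json.dumps(config.model_dump(), indent=2, sort_keys=True, default=str)
    )
    for condition, pc in per_condition.items():
        rows = []
        freqs = pc["freqs"]
        for i in range(freqs.size):
            rows.append({
                "subject": "grand", "condition": condition, "channel": "avg",
                "freq_bin": i, "freq_hz": float(freqs[i]),
                "E": float(pc["grand_E"][i]), "R": float(pc["grand_R"][i]),
                "I": float(pc["grand_I"][i]),
                "En": float(pc["grand_En"][i]) if np.isfinite(pc["grand_En"][i]) else "",
            })
        write_spectra_tsv(out_dir / f"spectra_{condition}.tsv", rows)
        write_tests_tsv(
            out_dir / f"tests_{condition}.tsv",
            pc["grand_tests"] + pc["subject_tests"],
        )
    if "behavior_scores" in report:
        n = len(report["behavior_scores"])
        write_behavior_tsv(
            out_dir / "behavior.tsv",
            [f"S{i:02d}" for i in range(n)],
            "sentence",
            np.array(report["behavior_scores"]),
        )
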