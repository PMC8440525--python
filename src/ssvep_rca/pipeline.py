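"""Study orchestration: simulate or load recordings, preprocess, extract
coefficients, run base and deviant analyses per condition and jointly, and
emit machine-readable report tables.

The pipeline adds no computation beyond sequencing the stage modules; the
fixed order is preprocess -> spectral -> RCA -> projection -> per-subject
averaging -> Hotelling T^2 + FDR -> latency (deviant analyses only).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _scipy_stats

from ssvep_rca import inferential, latency, preprocess, rca, spectral, synth

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionSpec",
    "StudyConfig",
    "AnalysisResult",
    "ConditionResult",
    "JointResult",
    "default_study",
    "default_truth",
    "simulate_study",
    "run_condition",
    "run_joint",
    "write_report",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSpec:
    """One stimulation condition: schedule parameters plus harmonic rules."""

    name: str
    base_hz: float
    items_per_deviant: int
    trial_duration_s: float = 12.0
    n_trials: int = 16
    n_harmonics: int = 4
    exclude_base_from_deviant: bool = True

    @property
    def deviant_hz(self) -> float:
        return self.base_hz / self.items_per_deviant

    def schedule(self) -> synth.StimulusSchedule:
        return synth.make_schedule(self.base_hz, self.items_per_deviant,
                                   self.trial_duration_s, self.n_trials)

    def base_harmonics(self) -> spectral.HarmonicSet:
        return spectral.enumerate_harmonics(self.base_hz, self.base_hz,
                                            self.n_harmonics)

    def deviant_harmonics(self) -> spectral.HarmonicSet:
        return spectral.enumerate_harmonics(
            self.deviant_hz, self.base_hz, self.n_harmonics,
            exclude_base=self.exclude_base_from_deviant,
        )


@dataclass(frozen=True)
class StudyConfig:
    conditions: tuple[ConditionSpec, ...]
    preprocessing: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig
    )
    n_deviant_components: int = 2
    n_base_components: int = 1
    rank_k: int | None = None
    alpha: float = 0.05
    n_subjects: int = 16
    fs_acquisition: float = 500.0
    n_sensors: int = 128
    seed: int = 0

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        conds = tuple(ConditionSpec(**c) for c in raw.pop("conditions"))
        pp = preprocess.PreprocessConfig(**raw.pop("preprocessing", {}))
        return cls(conditions=conds, preprocessing=pp, **raw)


def default_study(**overrides) -> StudyConfig:
    """Five-condition layout: 10/2 Hz oddball (x4) and 6/3 Hz alternation."""
    conditions = (
        ConditionSpec("cond1", base_hz=10.0, items_per_deviant=5),
        ConditionSpec("cond2", base_hz=10.0, items_per_deviant=5),
        ConditionSpec("cond3", base_hz=6.0, items_per_deviant=2),
        ConditionSpec("cond4", base_hz=10.0, items_per_deviant=5),
        ConditionSpec("cond5", base_hz=10.0, items_per_deviant=5),
    )
    return StudyConfig(conditions=conditions, **overrides)


# ---------------------------------------------------------------------------
# Synthetic study data
# ---------------------------------------------------------------------------

def default_truth(
    montage: synth.SensorMontage,
    spec: ConditionSpec,
    seed: int,
    deviant_tau_ms: tuple[float, float] = (180.0, 260.0),
    deviant_amps: tuple[tuple[float, ...], ...] = ((4.0, 3.0, 2.0, 1.2),
                                                   (2.5, 1.6, 1.0, 0.6)),
    base_tau_ms: float = 90.0,
    base_amps: tuple[float, ...] = (3.0, 1.5, 0.8, 0.4),
    noise_1f_scale: float = 2.0,
    noise_white_scale: float = 0.7,
    amp_jitter_frac: float = 0.2,
    latency_jitter_ms: float = 5.0,
) -> synth.GroundTruth:
    """Planted two-source deviant + one-source base ground truth.

    The two deviant sources have orthogonal smooth topographies and distinct
    group delays (defaults 180 and 260 ms); the base source responds at the
    base harmonic ladder.
    """
    rng = np.random.default_rng(seed)
    topos = []
    for _ in range(3):
        v = synth._smooth_random_topography(rng, montage)
        v = v - v.mean()  # zero-mean: invariant under average re-referencing
        for u in topos:
            v = v - (v @ u) * u
        v /= np.linalg.norm(v)
        topos.append(v)

    dev = spec.deviant_harmonics().frequencies
    base = spec.base_harmonics().frequencies
    sources = [
        synth.PlantedSource(topography=topos[0], freqs_hz=dev,
                            amps_uv=tuple(deviant_amps[0][: len(dev)]),
                            tau_ms=deviant_tau_ms[0]),
        synth.PlantedSource(topography=topos[1], freqs_hz=dev,
                            amps_uv=tuple(deviant_amps[1][: len(dev)]),
                            tau_ms=deviant_tau_ms[1]),
        synth.PlantedSource(topography=topos[2], freqs_hz=base,
                            amps_uv=tuple(base_amps[: len(base)]),
                            tau_ms=base_tau_ms),
    ]
    return synth.GroundTruth(
        sources=tuple(sources),
        noise_1f_scale=noise_1f_scale,
        noise_white_scale=noise_white_scale,
        amp_jitter_frac=amp_jitter_frac,
        latency_jitter_ms=latency_jitter_ms,
        seed=seed,
    )


def simulate_study(
    config: StudyConfig,
    truths: dict[str, synth.GroundTruth] | None = None,
) -> dict[str, list[synth.RawRecording]]:
    """Simulate recordings for every condition; returns condition -> list of
    per-subject recordings.  Ground truths default to :func:`default_truth`
    with per-condition seeds derived from ``config.seed``."""
    montage = synth.spherical_montage(config.n_sensors)
    data: dict[str, list[synth.RawRecording]] = {}
    for i, spec in enumerate(config.conditions):
        truth = (truths or {}).get(spec.name) or default_truth(
            montage, spec, seed=config.seed * 1000 + i
        )
        data[spec.name] = synth.simulate_recording(
            truth, spec.schedule(), montage, config.fs_acquisition,
            config.n_subjects, condition_id=spec.name,
        )
    return data


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    """One RCA analysis (base or deviant) for one training run."""

    role: str
    harmonics: spectral.HarmonicSet
    model: rca.RcaModel
    subject_means: np.ndarray       # (n_subjects, n_components, n_harmonics)
    subject_labels: list[str]
    tests: pd.DataFrame             # component, harmonic, t2, p, p_fdr, significant
    ellipses: dict[tuple[int, float], inferential.ErrorEllipse]
    latencies: list[latency.LatencyEstimate] = field(default_factory=list)
    phase_comparisons: pd.DataFrame | None = None

    def significant_matrix(self) -> np.ndarray:
        """(n_components, n_harmonics) significance flags from the tests table."""
        n_comp = self.model.n_components
        out = np.zeros((n_comp, self.harmonics.n), dtype=bool)
        for row in self.tests.itertuples():
            out[row.component, self.harmonics.frequencies.index(row.harmonic)] = \
                bool(row.significant)
        return out


@dataclass
class ConditionResult:
    name: str
    base: AnalysisResult
    deviant: AnalysisResult
    provenance: dict


@dataclass
class JointResult:
    condition_names: list[str]
    model: rca.RcaModel
    per_condition: dict[str, AnalysisResult]
    amplitude_comparison: pd.DataFrame


# ---------------------------------------------------------------------------
# Analysis stages
# ---------------------------------------------------------------------------

def _preprocess_all(recordings, cfg: StudyConfig):
    return [preprocess.run(r, cfg.preprocessing) for r in recordings]


def _analysis_from_projection(
    role: str,
    harmonics: spectral.HarmonicSet,
    model: rca.RcaModel,
    trials: rca.FeatureTrials,
    alpha: float,
    fdr_family: int | None = None,
) -> AnalysisResult:
    projected = rca.project(trials, model)
    means, labels = inferential.subject_means(projected, trials.subject_ids)

    rows = []
    for c in range(model.n_components):
        for h_idx, f in enumerate(harmonics.frequencies):
            res = inferential.hotelling_t2_zero(means[:, c, h_idx])
            rows.append({"component": c, "harmonic": f,
                         "t2": res.statistic, "p": res.p})
    tests = pd.DataFrame(rows)
    family = fdr_family if fdr_family is not None else len(tests)
    tests["p_fdr"] = inferential.fdr_adjust(tests["p"].to_numpy(), m=family)
    tests["significant"] = tests["p_fdr"] < alpha
    tests["fdr_family"] = family

    ellipses = {
        (c, f): inferential.error_ellipse(means[:, c, harmonics.frequencies.index(f)])
        for c in range(model.n_components) for f in harmonics.frequencies
    }
    result = AnalysisResult(role=role, harmonics=harmonics, model=model,
                            subject_means=means, subject_labels=labels,
                            tests=tests, ellipses=ellipses)

    if role == "deviant":
        sig = result.significant_matrix()
        result.latencies = [
            latency.estimate_component_latency(means[:, c], harmonics.frequencies,
                                               sig[c])
            for c in range(model.n_components)
        ]
        if model.n_components >= 2:
            result.phase_comparisons = _compare_component_phases(
                means, harmonics, sig, alpha
            )
    return result


def _compare_component_phases(
    means: np.ndarray,
    harmonics: spectral.HarmonicSet,
    sig: np.ndarray,
    alpha: float,
) -> pd.DataFrame:
    """Paired circular comparison of RC1 vs RC2 phases at harmonics
    significant for both components, FDR-corrected over that family."""
    both = np.nonzero(sig[0] & sig[1])[0]
    rows = []
    for h_idx in both:
        f = harmonics.frequencies[h_idx]
        ph1 = np.angle(means[:, 0, h_idx])
        ph2 = np.angle(means[:, 1, h_idx])
        try:
            p, dphi = inferential.circular_phase_test(ph1, ph2)
        except ValueError:
            continue
        rows.append({
            "harmonic": f, "mean_phase_diff_rad": dphi,
            "latency_diff_ms": inferential.phase_diff_to_latency(dphi, f),
            "p": p,
        })
    df = pd.DataFrame(rows, columns=["harmonic", "mean_phase_diff_rad",
                                     "latency_diff_ms", "p"])
    if len(df):
        df["p_fdr"] = inferential.fdr_adjust(df["p"].to_numpy())
        df["significant"] = df["p_fdr"] < alpha
    return df


def run_condition(
    recordings: list[synth.RawRecording],
    spec: ConditionSpec,
    cfg: StudyConfig,
) -> ConditionResult:
    """Full single-condition analysis in the fixed stage order.

    Base analysis: base harmonic ladder, one reported component, FDR family
    = n_harmonics.  Deviant analysis: deviant harmonic ladder, two
    components, FDR family = 2 x n_harmonics, plus latency estimation and
    circular phase comparison.
    """
    epoched = _preprocess_all(recordings, cfg)
    provenance = {
        "condition": spec.name,
        "n_subjects": len(recordings),
        "n_rejected_pairs": int(sum(e.provenance.get("n_rejected_pairs", 0)
                                    for e in epoched)),
        "n_repaired_sensors": int(sum(e.provenance.get("n_repaired_sensors", 0)
                                      for e in epoched)),
    }

    results = {}
    for role, harmonics, n_comp in (
        ("base", spec.base_harmonics(), cfg.n_base_components),
        ("deviant", spec.deviant_harmonics(), cfg.n_deviant_components),
    ):
        coeffs = [spectral.spectral_coefficients(e, harmonics) for e in epoched]
        trials = rca.build_feature_trials(coeffs)
        model = rca.train_rca(trials, n_components=n_comp, rank_k=cfg.rank_k)
        model = rca.align_signs(model, trials)
        results[role] = _analysis_from_projection(
            role, harmonics, model, trials, cfg.alpha,
            fdr_family=n_comp * harmonics.n,
        )
    return ConditionResult(name=spec.name, base=results["base"],
                           deviant=results["deviant"], provenance=provenance)


def run_joint(
    recordings_by_condition: dict[str, list[synth.RawRecording]],
    specs: list[ConditionSpec],
    cfg: StudyConfig,
) -> JointResult:
    """Train one deviant-analysis model on pooled conditions, then project
    and test each condition in the shared component space; per-harmonic
    amplitudes are compared between the first two conditions."""
    if len(specs) < 2:
        raise ValueError("joint analysis needs at least 2 conditions")
    layouts = {(s.n_harmonics,) for s in specs}
    if len(layouts) != 1:
        raise ValueError("conditions have mismatched harmonic layouts")

    trials_by_cond = {}
    for spec in specs:
        epoched = _preprocess_all(recordings_by_condition[spec.name], cfg)
        harmonics = spec.deviant_harmonics()
        coeffs = [spectral.spectral_coefficients(e, harmonics) for e in epoched]
        trials_by_cond[spec.name] = rca.build_feature_trials(coeffs)

    model = rca.train_joint(list(trials_by_cond.values()),
                            n_components=cfg.n_deviant_components,
                            rank_k=cfg.rank_k)
    model = rca.align_signs(model, trials_by_cond[specs[0].name])

    per_condition = {
        spec.name: _analysis_from_projection(
            "deviant", spec.deviant_harmonics(), model,
            trials_by_cond[spec.name], cfg.alpha,
            fdr_family=cfg.n_deviant_components * spec.n_harmonics,
        )
        for spec in specs
    }

    a, b = specs[0].name, specs[1].name
    amp_rows = []
    common_subjects = sorted(set(per_condition[a].subject_labels)
                             & set(per_condition[b].subject_labels))
    ia = [per_condition[a].subject_labels.index(s) for s in common_subjects]
    ib = [per_condition[b].subject_labels.index(s) for s in common_subjects]
    for c in range(model.n_components):
        for h_idx, f in enumerate(specs[0].deviant_harmonics().frequencies):
            amp_a = np.abs(per_condition[a].subject_means[ia, c, h_idx])
            amp_b = np.abs(per_condition[b].subject_means[ib, c, h_idx])
            t, p = _scipy_stats.ttest_rel(amp_a, amp_b)
            amp_rows.append({"component": c, "harmonic": f,
                             "t": float(t), "p": float(p)})
    return JointResult(
        condition_names=[s.name for s in specs],
        model=model,
        per_condition=per_condition,
        amplitude_comparison=pd.DataFrame(amp_rows),
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _latency_rows(name: str, result: AnalysisResult):
    for c, est in enumerate(result.latencies):
        yield {
            "condition": name, "component": c,
            "estimable": est.estimable,
            "tau_ms": est.tau_ms if est.estimable else None,
            "se_ms": est.se_ms,
            "harmonics_used": ";".join(str(f) for f in est.harmonics_used),
            "reason": est.reason,
        }


def write_report(
    results: list[ConditionResult],
    out_dir: Path,
    config: StudyConfig | None = None,
    joint: JointResult | None = None,
) -> dict[str, Path]:
    """Emit tidy CSV tables plus a JSON provenance record.

    Regeneration from the same config and data is byte-identical.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out_dir}: {exc}") from exc

    tests, topo, reliab, lat, phase = [], [], [], [], []
    for res in results:
        for role in ("base", "deviant"):
            ana: AnalysisResult = getattr(res, role)
            t = ana.tests.copy()
            t.insert(0, "condition", res.name)
            t.insert(1, "analysis", role)
            tests.append(t)
            for c in range(ana.model.n_components):
                reliab.append({
                    "condition": res.name, "analysis": role, "component": c,
                    "reliability_pct": 100.0 * ana.model.reliability_fraction[c],
                })
                for s in range(ana.model.A.shape[0]):
                    topo.append({"condition": res.name, "analysis": role,
                                 "component": c, "sensor": s,
                                 "weight": ana.model.A[s, c]})
        lat.extend(_latency_rows(res.name, res.deviant))
        if res.deviant.phase_comparisons is not None and len(res.deviant.phase_comparisons):
            pc = res.deviant.phase_comparisons.copy()
            pc.insert(0, "condition", res.name)
            phase.append(pc)

    paths: dict[str, Path] = {}

    def _write(key: str, frame: pd.DataFrame) -> None:
        p = out_dir / f"{key}.csv"
        frame.to_csv(p, index=False)
        paths[key] = p

    if tests:
        _write("tests", pd.concat(tests, ignore_index=True))
    if reliab:
        _write("reliability", pd.DataFrame(reliab))
    if topo:
        _write("topographies", pd.DataFrame(topo))
    if lat:
        _write("latencies", pd.DataFrame(lat))
    if phase:
        _write("phase_comparisons", pd.concat(phase, ignore_index=True))
    if len(results) >= 2:
        xcorr = []
        for i, ra in enumerate(results):
            for rb in results[i + 1:]:
                for role in ("base", "deviant"):
                    Aa = getattr(ra, role).model.A
                    Ab = getattr(rb, role).model.A
                    if Aa.shape != Ab.shape:
                        continue
                    for c in range(Aa.shape[1]):
                        xcorr.append({
                            "condition_a": ra.name, "condition_b": rb.name,
                            "analysis": role, "component": c,
                            "r": rca.topography_correlation(Aa[:, c], Ab[:, c]),
                        })
        if xcorr:
            _write("topography_correlations", pd.DataFrame(xcorr))
    if joint is not None:
        _write("joint_amplitude_comparison", joint.amplitude_comparison)

    provenance = {
        "config_hash": config.config_hash() if config else None,
        "seed": config.seed if config else None,
        "conditions": [r.provenance for r in results],
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=1, sort_keys=True))
    paths["provenance"] = prov_path
    return paths
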