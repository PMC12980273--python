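"""End-to-end orchestration: simulate -> extract -> classify -> report.

`run_pipeline` produces a deterministic artefact directory from a
single seed: the panel manifest, the effect matrix, PC score tables,
the posterior table, the MPS table with ranking, PCA loadings, and a
log recording versions, parameters, dropped features and warnings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .features import BandScheme, SpectralParams, panel_effect_matrix
from .io import (
    write_effect_matrix,
    write_mps_table,
    write_posterior_table,
    write_score_table,
)
from .model import ClassificationResult, classify_group, loadings_frame
from .sim import (
    BaselineSpec,
    DrugSignature,
    Panel,
    default_signatures,
    generate_panel,
    load_panel_config,
    save_panel,
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; everything is seeded."""

    seed: int = 0
    n_per_group: int = 10
    duration_s: float = 60.0
    jitter_sd: float = 0.1
    k: int = 6
    pca_population: Literal["training", "all"] = "training"
    priors: Literal["uniform", "empirical"] = "uniform"
    variance_floor: float = 1e-9
    panel_config: str | None = None  # YAML path; None -> default 19-group panel
    test_panel_config: str | None = None  # optional held-out test signatures
    save_recordings: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"run config not found: {path}")
        try:
            doc = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{path}: invalid YAML: {exc}") from None
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _resolve_signatures(
    config: RunConfig,
) -> tuple[BaselineSpec, list[DrugSignature], list[DrugSignature] | None]:
    if config.panel_config is not None:
        baseline, train_sigs = load_panel_config(config.panel_config)
        baseline = BaselineSpec(
            fs=baseline.fs,
            duration_s=config.duration_s,
            band_amplitudes=baseline.band_amplitudes,
            noise_floor=baseline.noise_floor,
        )
    else:
        baseline = BaselineSpec(duration_s=config.duration_s)
        train_sigs = default_signatures(jitter_sd=config.jitter_sd)
    test_sigs = None
    if config.test_panel_config is not None:
        _, test_sigs = load_panel_config(config.test_panel_config)
    return baseline, train_sigs, test_sigs


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write all artefacts under ``out_dir``.

    Returns a dict with the artefact paths and the in-memory
    :class:`~pharmeeg.model.ClassificationResult`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    stamp = f"pharmeeg {__version__} seed={config.seed} config={config.config_hash()} mode={config.pca_population}"
    log(stamp)

    baseline, train_sigs, test_sigs = _resolve_signatures(config)
    train_seed, test_seed = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(config.seed).spawn(2)
    ]
    log(f"[simulate] {len(train_sigs)} training groups x {config.n_per_group} records, "
        f"duration {baseline.duration_s} s, jitter_sd {config.jitter_sd}")
    panel = generate_panel(train_sigs, config.n_per_group, train_seed, baseline)
    test_panel: Panel | None = None
    if test_sigs is not None:
        test_panel = generate_panel(test_sigs, config.n_per_group, test_seed, baseline)
        log(f"[simulate] {len(test_sigs)} test groups x {config.n_per_group} records")

    manifest_path = out_dir / "manifest.csv"
    panel.manifest.to_csv(manifest_path, index=False, lineterminator="\n")
    if config.save_recordings:
        save_panel(panel, out_dir / "recordings")
        if test_panel is not None:
            save_panel(test_panel, out_dir / "recordings_test")

    scheme = BandScheme()
    params = SpectralParams(fs=baseline.fs)
    log("[extract] 132 amplitude-spectral features per record")
    train_effects = panel_effect_matrix(panel.pairs, scheme, params)
    test_effects = (
        panel_effect_matrix(test_panel.pairs, scheme, params)
        if test_panel is not None
        else train_effects
    )
    effects_path = out_dir / "effect_matrix.csv"
    write_effect_matrix(train_effects, effects_path)
    if test_panel is not None:
        write_effect_matrix(test_effects, out_dir / "effect_matrix_test.csv")

    log(f"[classify] PCA k={config.k}, population={config.pca_population}, "
        f"priors={config.priors}")
    result: ClassificationResult = classify_group(
        train_effects,
        test_effects,
        k=config.k,
        pca_population=config.pca_population,
        priors=config.priors,
        variance_floor=config.variance_floor,
    )
    if result.pca.dropped_features:
        log(f"[classify] dropped near-constant feature(s): {result.pca.dropped_features}")
    log(f"[classify] eigenvalue spectrum head: "
        f"{np.round(result.pca.eigenvalues[:config.k], 3).tolist()}")
    log(f"[classify] explained variance (first {config.k}): "
        f"{float(result.pca.evr[:config.k].sum()):.4f}")

    scores_path = out_dir / "scores.csv"
    write_score_table(result.train_scores, scores_path)
    write_score_table(result.test_scores, out_dir / "scores_test.csv")
    posteriors_path = out_dir / "posteriors.csv"
    write_posterior_table(result.posteriors, posteriors_path)
    mps_path = out_dir / "mps.csv"
    write_mps_table(result.mps.table, mps_path)
    result.mps.ranking.to_csv(out_dir / "mps_ranking.csv", index=False, lineterminator="\n")
    loadings_frame(result.pca).to_csv(out_dir / "loadings.csv", lineterminator="\n")

    for _, row in result.mps.ranking.iterrows():
        flag = " (tie)" if row["tied"] else ""
        log(f"[report] {row['group']}: top class {row['top_class']} (MPS {row['mps']:.3f}){flag}")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    return {
        "out_dir": out_dir,
        "manifest": manifest_path,
        "effect_matrix": effects_path,
        "scores": scores_path,
        "posteriors": posteriors_path,
        "mps": mps_path,
        "log": out_dir / "run.log",
        "result": result,
    }
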