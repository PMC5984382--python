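"""End-to-end pipeline: simulate → preprocess → extract → evaluate → permute.

A :class:`PipelineConfig` fully determines a run; one master seed derives the
seeds of every stochastic stage, so a rerun with the same config reproduces
the reports byte for byte. The run directory layout is fixed:

    run_dir/
      config.json          # snapshot of the resolved configuration
      inputs/              # per-subject CSVs + labels manifest (optional)
      features/            # feature matrix CSV per extraction method
      models/              # full-data tree (JSON + rules) per problem
      reports/             # evaluation + permutation JSON reports
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, fourier, wavelet
from .matrix import FeatureMatrix, assemble_matrix
from .io_signals import preprocess, write_csv
from .synthetic_cohort import SyntheticCohortConfig, generate_cohort
from .tree import export_rules, train_c45

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    methods: tuple[str, ...] = ("fourier", "wavelet")
    problems: tuple[str, ...] = ("HCvsAD", "HCvsMCI", "MCIvsAD", "HCvsCASE")
    scheme: str = "loocv"
    trim_start_s: float = 60.0
    trim_end_s: float = 240.0
    target_fs: float = 256.0
    min_leaf: int = 2
    cf: float = 0.25
    top_k: int | None = None
    n_perm: int = 0              # 0 disables the permutation control
    seed: int = 0
    write_inputs: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["problems"] = list(self.problems)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cohort = dict(d["cohort"])
            if "band_defs" in cohort:
                cohort["band_defs"] = {
                    k: tuple(v) for k, v in cohort["band_defs"].items()}
            d["cohort"] = SyntheticCohortConfig(**cohort)
        for key in ("methods", "problems"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    tag = zlib.crc32(stage.encode()) % (2 ** 31)
    ss = np.random.SeedSequence([master, tag])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def extract_features(recordings, labels, method: str,
                     do_preprocess: bool = True, start_s: float = 60.0,
                     end_s: float = 240.0,
                     target_fs: float = 256.0) -> FeatureMatrix:
    """Preprocess and run one feature extractor over a list of recordings."""
    if method == "fourier":
        extractor = fourier.extract_fourier_features
        namer = fourier.fourier_feature_names
    elif method == "wavelet":
        extractor = wavelet.extract_wavelet_features
        namer = wavelet.wavelet_feature_names
    else:
        raise ValueError(f"unknown feature method {method!r}")
    vectors = []
    names = None
    for rec in recordings:
        if do_preprocess:
            rec = preprocess(rec, start_s=start_s, end_s=end_s,
                             target_fs=target_fs)
        vectors.append(extractor(rec))
        if names is None:
            names = namer(rec.channel_labels)
    ids = [f"sample_{i}" for i in range(len(vectors))]
    return assemble_matrix(vectors, labels, feature_names=names,
                           sample_ids=ids)


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> Path:
    """Execute every stage and populate the run directory; returns its path."""
    run_dir = Path(run_dir)
    for sub in ("inputs", "features", "models", "reports"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    (run_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True))

    def stage(name):
        t0 = time.time()

        def done(count):
            logger.info("stage %-10s done: %d records in %.1f s",
                        name, count, time.time() - t0)
        return done

    try:
        done = stage("simulate")
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=derive_seed(config.seed, "simulate"))
        recordings, labels = generate_cohort(cohort_cfg)
        done(len(recordings))
        if config.write_inputs:
            manifest = ["subject_id,label"]
            for i, (rec, lab) in enumerate(zip(recordings, labels)):
                write_csv(rec, run_dir / "inputs" / f"subject_{i:03d}.csv")
                manifest.append(f"subject_{i:03d},{lab}")
            (run_dir / "inputs" / "labels.csv").write_text(
                "\n".join(manifest) + "\n")
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    matrices: dict[str, FeatureMatrix] = {}
    for method in config.methods:
        try:
            done = stage(f"extract/{method}")
            matrices[method] = extract_features(
                recordings, labels, method,
                start_s=config.trim_start_s, end_s=config.trim_end_s,
                target_fs=config.target_fs)
            matrices[method].to_csv(run_dir / "features" / f"{method}.csv")
            done(matrices[method].n_samples)
        except Exception as exc:
            raise RuntimeError(f"stage extract/{method} failed: {exc}") from exc

    reports: dict[str, dict] = {}
    for method, matrix in matrices.items():
        for problem in config.problems:
            try:
                done = stage(f"evaluate/{method}/{problem}")
                binary = evaluation.make_problem(matrix, problem)
                tree = train_c45(binary, min_leaf=config.min_leaf,
                                 cf=config.cf)
                base = run_dir / "models" / f"{method}_{problem}"
                base.with_suffix(".json").write_text(tree.to_json())
                base.with_suffix(".rules").write_text(export_rules(tree) + "\n")
                report = evaluation.cross_validate(
                    binary, scheme=config.scheme,
                    seed=derive_seed(config.seed, f"cv/{method}/{problem}"),
                    min_leaf=config.min_leaf, cf=config.cf,
                    problem=problem, top_k=config.top_k)
                entry = report.to_dict()
                if config.n_perm > 0:
                    accs, mean = evaluation.permutation_test(
                        binary, n_perm=config.n_perm, scheme=config.scheme,
                        seed=derive_seed(config.seed,
                                         f"perm/{method}/{problem}"),
                        min_leaf=config.min_leaf, cf=config.cf)
                    entry["permutation"] = {
                        "n_perm": config.n_perm,
                        "accuracies": accs.tolist(), "mean": mean}
                entry["seed"] = config.seed
                reports[f"{method}/{problem}"] = entry
                done(report.n_folds)
            except Exception as exc:
                raise RuntimeError(
                    f"stage evaluate/{method}/{problem} failed: {exc}"
                ) from exc

    (run_dir / "reports" / "evaluation.json").write_text(
        json.dumps(reports, indent=1, sort_keys=True))
    return run_dir
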