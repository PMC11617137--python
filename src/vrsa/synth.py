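"""Synthetic data with a known, planted component structure.

Voxel patterns are drawn i.i.d. across voxels from a zero-mean Gaussian over
the 8 conditions whose covariance is the specified mixture of component model
matrices plus isotropic noise — exactly the generative model assumed by the
pattern component fit, so planted weights are the ground truth the pipeline
should recover.  BOLD time series can additionally be generated from a run
design via HRF convolution to exercise the GLM stage end to end.

The generator draws exchangeable voxels with white noise; it does not emulate
spatial smoothness, scanner drift, or physiological autocorrelation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .components import COMPONENT_NAMES, component_matrices
from .glm import PatternMatrix
from .task_design import CONDITION_LABELS, DesignMatrix, RunDesign

__all__ = [
    "GenerativeSpec",
    "SyntheticDataset",
    "generate_patterns",
    "generate_bold",
    "make_fixture",
]

#: Default planted effects: one gaze-centric distance component and one
#: direction component at half the voxel noise variance — a moderate,
#: detectable-but-not-trivial signal-to-noise regime for a reach ROI.
DEFAULT_WEIGHTS = {"ET_dist": 0.5, "T_dir": 0.5}

FIXTURE_PROFILES = {
    # 4 subjects x 2 runs x 200 voxels: seconds to fit, used throughout tests.
    "tiny": dict(n_subjects=4, n_runs=2, n_voxels=200),
    # Matches the study conditions: 27 subjects, 6 runs, ~2000-voxel ROI.
    "paper_scale": dict(n_subjects=27, n_runs=6, n_voxels=2000),
}


@dataclass(frozen=True)
class GenerativeSpec:
    """Ground-truth settings for pattern generation.

    ``weights`` maps component names to planted variances w_c >= 0;
    ``noise_var`` is the isotropic voxel noise variance per run.
    ``subject_sd`` scales optional lognormal between-subject jitter of the
    weights (0 = identical subjects).  ``mean_amplitude`` adds a shared
    condition-independent pattern (off by default; the model centers it out).
    """

    weights: dict[str, float] = field(default_factory=dict)
    noise_var: float = 1.0
    n_voxels: int = 200
    n_subjects: int = 27
    n_runs: int = 6
    rng_seed: int = 0
    subject_sd: float = 0.0
    mean_amplitude: float = 0.0

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if name not in COMPONENT_NAMES:
                raise KeyError(f"unknown component {name!r}")
            if w < 0:
                raise ValueError("component weights must be >= 0")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")
        if self.noise_var == 0 and not any(self.weights.values()):
            raise ValueError("need a positive noise variance or component weight")
        if min(self.n_voxels, self.n_subjects, self.n_runs) < 1:
            raise ValueError("counts must be >= 1")

    def covariance(self, weights: dict[str, float] | None = None) -> np.ndarray:
        """Expected 8x8 condition covariance sum_c w_c G_c + noise_var * I."""
        w = self.weights if weights is None else weights
        Gc = component_matrices()
        Sigma = self.noise_var * np.eye(8)
        for name, wc in w.items():
            Sigma = Sigma + wc * Gc[name]
        return Sigma


@dataclass
class SyntheticDataset:
    """Per-subject/run pattern matrices with their generative ground truth."""

    spec: GenerativeSpec
    patterns: dict[tuple[int, int], PatternMatrix]  # (subject, run) -> U
    true_G: dict[int, np.ndarray]  # subject -> expected condition covariance
    subject_weights: dict[int, dict[str, float]]

    @property
    def subjects(self) -> list[int]:
        return sorted({s for s, _ in self.patterns})

    def runs(self, subject: int) -> list[PatternMatrix]:
        return [
            self.patterns[(s, r)]
            for s, r in sorted(self.patterns)
            if s == subject
        ]

    def save(self, out_dir) -> None:
        """TSV per subject/run plus a JSON manifest with the spec and seed."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for (s, r), pm in sorted(self.patterns.items()):
            fname = f"sub-{s:02d}_run-{r:02d}_U.tsv"
            pm.to_tsv(out / fname)
            entries.append({"subject": s, "run": r, "file": fname})
        manifest = {
            "format": "vrsa-synthetic-dataset",
            "spec": asdict(self.spec),
            "condition_labels": list(CONDITION_LABELS),
            "patterns": entries,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, manifest_path) -> "SyntheticDataset":
        from pathlib import Path

        path = Path(manifest_path)
        manifest = json.loads(path.read_text())
        spec = GenerativeSpec(**manifest["spec"])
        patterns = {}
        for e in manifest["patterns"]:
            patterns[(e["subject"], e["run"])] = PatternMatrix.from_tsv(
                path.parent / e["file"], subject=e["subject"], run=e["run"]
            )
        ds = generate_patterns(spec)  # regenerate truth deterministically
        return cls(
            spec=spec,
            patterns=patterns,
            true_G=ds.true_G,
            subject_weights=ds.subject_weights,
        )


def generate_patterns(spec: GenerativeSpec) -> SyntheticDataset:
    """Draw condition-by-voxel pattern matrices for every subject and run."""
    rng = np.random.default_rng(spec.rng_seed)
    patterns: dict[tuple[int, int], PatternMatrix] = {}
    true_G: dict[int, np.ndarray] = {}
    subject_weights: dict[int, dict[str, float]] = {}
    for s in range(spec.n_subjects):
        if spec.subject_sd > 0:
            jitter = np.exp(rng.normal(0.0, spec.subject_sd, size=len(spec.weights)))
            w = {k: v * j for (k, v), j in zip(spec.weights.items(), jitter)}
        else:
            w = dict(spec.weights)
        subject_weights[s] = w
        Sigma = spec.covariance(w)
        true_G[s] = Sigma
        L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(8))
        for r in range(spec.n_runs):
            U = L @ rng.standard_normal((8, spec.n_voxels))
            if spec.mean_amplitude:
                U = U + spec.mean_amplitude * rng.standard_normal(spec.n_voxels)
            patterns[(s, r)] = PatternMatrix(
                values=U, subject=s, run=r, epoch="synthetic"
            )
    return SyntheticDataset(
        spec=spec, patterns=patterns, true_G=true_G, subject_weights=subject_weights
    )


def generate_bold(
    run: RunDesign,
    condition_amplitudes: np.ndarray,
    noise_sd: float,
    rng_seed: int | np.random.Generator,
    X: DesignMatrix | None = None,
) -> tuple[np.ndarray, DesignMatrix]:
    """Simulate BOLD time series y = X beta + white noise for one run.

    ``condition_amplitudes`` has one row per task column of the generative
    design (by default :func:`~vrsa.task_design.build_generative_matrix`,
    whose task columns are the early- then late-epoch condition regressors in
    canonical order) and one column per voxel.  Returns ``(y, X)`` with
    ``y`` of shape (n_scans, n_voxels).
    """
    from .task_design import build_generative_matrix

    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if X is None:
        X = build_generative_matrix(run)
    amplitudes = np.atleast_2d(np.asarray(condition_amplitudes, dtype=float))
    task_idx = [i for i, f in enumerate(X.task) if f]
    if amplitudes.shape[0] != len(task_idx):
        raise ValueError(
            f"expected {len(task_idx)} amplitude rows (one per task regressor), "
            f"got {amplitudes.shape[0]}"
        )
    beta = np.zeros((X.values.shape[1], amplitudes.shape[1]))
    beta[task_idx] = amplitudes
    y = X.values @ beta
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(y.shape)
    return y, X


def make_fixture(
    profile: str = "tiny",
    rng_seed: int = 0,
    weights: dict[str, float] | None = None,
    noise_var: float = 1.0,
    out_dir=None,
) -> SyntheticDataset:
    """Standard test datasets: ``tiny`` (4 x 2 x 200) or ``paper_scale`` (27 x 6 x 2000)."""
    if profile not in FIXTURE_PROFILES:
        raise KeyError(f"unknown profile {profile!r}; expected {sorted(FIXTURE_PROFILES)}")
    spec = GenerativeSpec(
        weights=dict(DEFAULT_WEIGHTS if weights is None else weights),
        noise_var=noise_var,
        rng_seed=rng_seed,
        **FIXTURE_PROFILES[profile],
    )
    ds = generate_patterns(spec)
    if out_dir is not None:
        ds.save(out_dir)
    return ds
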