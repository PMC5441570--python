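"""Synthetic multi-site fMRI-like cohort generator with planted connectivity effects.

Emulates the structure of a multi-site case/control task-fMRI study: several
acquisition sites with per-site "batch" distortions, two groups (patients and
controls), a fixed number of runs per subject, and integer 0-5 symptom-severity
scales for patients. Ground truth is planted at the supervoxel level: a chosen
set of node pairs is hyperconnected in patients (correlation elevated by
``delta_r``), and the symptom scales are a sparse linear function of the
subject's realized planted-link correlations. Every downstream stage of the
pipeline therefore has a recovery test against known truth.

The generative model, per subject:

1. a supervoxel-level correlation matrix: compound-symmetric baseline
   ``base_corr`` everywhere, plus ``delta_r`` on planted links for patients,
   plus a per-subject Gaussian perturbation of the planted entries
   (``subject_corr_sd``) modelling between-subject connectivity heterogeneity;
   repaired to positive semi-definite by eigenvalue clipping;
2. per run, a zero-mean Gaussian latent time series with that instantaneous
   correlation (Cholesky construction);
3. voxel series = the containing block's latent series plus i.i.d. voxel noise
   (``voxel_noise_sd``), then a per-site, per-voxel affine distortion
   (offset ~ N(0, site_offset_sd), scale ~ exp N(0, site_scale_sd)) drawn once
   per site;
4. for patients, each symptom scale is an equal-width 6-level binning of
   ``sum_L w_L (r_L - mu_L) + noise`` where ``r_L`` is the subject's mean
   planted-link correlation across runs (computed on the latent series, i.e.
   before scanner distortion).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticConfig",
    "CohortSample",
    "RunTimeSeries",
    "fbirn_like_config",
    "generate_cov_structure",
    "simulate_gaussian_series",
    "generate_run",
    "generate_scales",
    "generate_cohort",
    "iter_cohort",
    "write_cohort",
    "read_cohort",
]

PATIENT = "patient"
CONTROL = "control"


def _as_counts(value, n_sites: int, name: str) -> tuple[int, ...]:
    if np.isscalar(value):
        counts = (int(value),) * n_sites
    else:
        counts = tuple(int(v) for v in value)
        if len(counts) != n_sites:
            raise ValueError(f"{name} must have one entry per site ({n_sites})")
    if any(c < 1 for c in counts):
        raise ValueError(f"{name} entries must be >= 1")
    return counts


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``patients_per_site`` / ``controls_per_site`` accept either a single count
    applied to every site or a per-site sequence (allowing uneven cohorts such
    as 46 patients / 49 controls over five sites).
    """

    n_sites: int = 5
    patients_per_site: int | Sequence[int] = 9
    controls_per_site: int | Sequence[int] = 10
    runs_per_subject: int = 4
    grid_dims: tuple[int, int, int] = (8, 8, 6)
    block_dims: tuple[int, int, int] = (4, 4, 3)
    T: int = 137
    base_corr: float = 0.1
    planted_links: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5))
    delta_r: float = 0.25
    site_offset_sd: float = 0.5
    site_scale_sd: float = 0.2
    subject_corr_sd: float = 0.15
    voxel_noise_sd: float = 0.5
    scale_weights: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(0, 1): 1.0, (2, 3): 0.8, (4, 5): 0.6}
    )
    scale_noise_sd: float = 0.25
    n_scales: int = 9
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "grid_dims", tuple(int(d) for d in self.grid_dims))
        object.__setattr__(self, "block_dims", tuple(int(d) for d in self.block_dims))
        object.__setattr__(
            self,
            "planted_links",
            tuple(tuple(sorted((int(i), int(j)))) for i, j in self.planted_links),
        )
        object.__setattr__(
            self,
            "scale_weights",
            {tuple(sorted((int(i), int(j)))): float(w) for (i, j), w in self.scale_weights.items()},
        )
        self.validate()

    # -- derived geometry ---------------------------------------------------
    @property
    def super_dims(self) -> tuple[int, int, int]:
        return tuple(g // b for g, b in zip(self.grid_dims, self.block_dims))

    @property
    def n_supervoxels(self) -> int:
        return int(np.prod(self.super_dims))

    @property
    def patient_counts(self) -> tuple[int, ...]:
        return _as_counts(self.patients_per_site, self.n_sites, "patients_per_site")

    @property
    def control_counts(self) -> tuple[int, ...]:
        return _as_counts(self.controls_per_site, self.n_sites, "controls_per_site")

    @property
    def n_subjects(self) -> int:
        return sum(self.patient_counts) + sum(self.control_counts)

    @property
    def scale_names(self) -> tuple[str, ...]:
        return tuple(f"scale_{i + 1}" for i in range(self.n_scales))

    def validate(self) -> None:
        if self.n_sites < 1 or self.runs_per_subject < 1 or self.n_scales < 1:
            raise ValueError("all counts must be >= 1")
        _ = self.patient_counts, self.control_counts
        if self.T < 3:
            raise ValueError("T must be >= 3")
        if len(self.grid_dims) != 3 or len(self.block_dims) != 3:
            raise ValueError("grid_dims and block_dims must be integer triples")
        if any(g % b != 0 for g, b in zip(self.grid_dims, self.block_dims)):
            raise ValueError("block_dims must divide grid_dims for the generator")
        if not 0.0 <= self.base_corr < 1.0:
            raise ValueError("base_corr must be in [0, 1)")
        if self.delta_r < 0:
            raise ValueError("delta_r must be >= 0")
        if self.base_corr + self.delta_r >= 1.0:
            raise ValueError("base_corr + delta_r must be < 1")
        n = self.n_supervoxels
        for i, j in self.planted_links:
            if not (0 <= i < j < n):
                raise ValueError(f"planted link ({i}, {j}) outside supervoxel range 0..{n - 1}")
        for link in self.scale_weights:
            if link not in self.planted_links:
                raise ValueError(f"scale_weights key {link} is not a planted link")
        if self.scale_noise_sd < 0 or self.subject_corr_sd < 0 or self.voxel_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def fbirn_like_config(**overrides) -> SyntheticConfig:
    """A default cohort mirroring the published study layout.

    Five sites, 46 patients and 49 controls (95 subjects), 4 runs each
    (380 run samples), 137 time points per run.
    """
    params = dict(
        n_sites=5,
        patients_per_site=(9, 9, 9, 9, 10),
        controls_per_site=(10, 10, 10, 10, 9),
        runs_per_subject=4,
        T=137,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass(frozen=True)
class CohortSample:
    """One run of one subject: the unit row of every feature matrix."""

    subject_id: str
    run_id: int
    site_id: str
    group: str
    scales: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in (PATIENT, CONTROL):
            raise ValueError(f"group must be '{PATIENT}' or '{CONTROL}'")
        for name, v in self.scales.items():
            if v is not None and v not in (0, 1, 2, 3, 4, 5):
                raise ValueError(f"scale {name} value {v} outside 0..5")


@dataclass
class RunTimeSeries:
    """Node x time matrix on a 3-D voxel grid with a binary mask."""

    node_coords: np.ndarray  # (n_nodes, 3) int
    series: np.ndarray  # (n_nodes, T) float
    mask: np.ndarray  # 3-D bool

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=int)
        self.series = np.asarray(self.series, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.series.shape[0] != self.node_coords.shape[0]:
            raise ValueError("series must have one row per node")
        if not self.mask[tuple(self.node_coords.T)].all():
            raise ValueError("every node coordinate must lie inside the mask")

    @property
    def n_nodes(self) -> int:
        return self.series.shape[0]

    @property
    def T(self) -> int:
        return self.series.shape[1]


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def _psd_repair(corr: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and re-normalize to unit diagonal."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= -tol:
        return corr
    w = np.clip(w, 0.0, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    d[d == 0] = 1.0
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


def generate_cov_structure(config: SyntheticConfig, group: str) -> np.ndarray:
    """Supervoxel-level correlation matrix for one group.

    Compound-symmetric baseline ``base_corr``; for patients the planted links
    get ``+delta_r``. Repaired to PSD by eigenvalue clipping; if the repair
    moves any planted or baseline entry by more than 0.05 the configuration is
    rejected (the requested effect is incompatible with a valid correlation
    matrix).
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError("group must be 'patient' or 'control'")
    n = config.n_supervoxels
    m = np.full((n, n), config.base_corr, dtype=float)
    np.fill_diagonal(m, 1.0)
    if group == PATIENT:
        for i, j in config.planted_links:
            m[i, j] += config.delta_r
            m[j, i] += config.delta_r
    repaired = _psd_repair(m)
    if np.abs(repaired - m).max() > 0.05:
        raise ValueError(
            "requested planted correlations cannot be repaired into a valid "
            "correlation matrix; reduce delta_r or base_corr"
        )
    return repaired


def _subject_cov(config: SyntheticConfig, group: str, rng: np.random.Generator) -> np.ndarray:
    """Per-subject covariance: group matrix with jittered planted entries."""
    m = generate_cov_structure(config, group)
    if config.subject_corr_sd > 0 and config.planted_links:
        for i, j in config.planted_links:
            r = m[i, j] + rng.normal(0.0, config.subject_corr_sd)
            r = float(np.clip(r, -0.9, 0.9))
            m[i, j] = m[j, i] = r
        m = _psd_repair(m)
    return m


# ---------------------------------------------------------------------------
# time-series simulation
# ---------------------------------------------------------------------------

def simulate_gaussian_series(cov: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    """T samples of a zero-mean Gaussian process with instantaneous covariance."""
    cov = np.asarray(cov, dtype=float)
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-8:
        raise ValueError("covariance matrix is not positive semi-definite")
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    return chol @ rng.standard_normal((cov.shape[0], T))


def _full_mask_geometry(config: SyntheticConfig):
    """Voxel coordinates (C order) and their supervoxel (block) index."""
    gx, gy, gz = config.grid_dims
    coords = np.argwhere(np.ones(config.grid_dims, dtype=bool))
    blocks = coords // np.array(config.block_dims)
    sup_dims = config.super_dims
    block_index = np.ravel_multi_index(blocks.T, sup_dims)
    return coords, block_index


def generate_run(
    config: SyntheticConfig,
    cov: np.ndarray,
    rng: np.random.Generator,
    site_offset: np.ndarray | None = None,
    site_scale: np.ndarray | None = None,
    latent: np.ndarray | None = None,
) -> RunTimeSeries:
    """One run: voxel series from a supervoxel latent plus voxel noise and
    per-site affine distortion. Deterministic given the rng state."""
    if latent is None:
        latent = simulate_gaussian_series(cov, config.T, rng)
    coords, block_index = _full_mask_geometry(config)
    series = latent[block_index]
    if config.voxel_noise_sd > 0:
        series = series + config.voxel_noise_sd * rng.standard_normal(series.shape)
    else:
        series = series.copy()
    if site_scale is not None:
        series *= site_scale[:, None]
    if site_offset is not None:
        series += site_offset[:, None]
    mask = np.ones(config.grid_dims, dtype=bool)
    return RunTimeSeries(node_coords=coords, series=series, mask=mask)


# ---------------------------------------------------------------------------
# symptom scales
# ---------------------------------------------------------------------------

def _scale_theoretical_sd(config: SyntheticConfig) -> float:
    """Theoretical SD of the latent symptom score under the generative model.

    Per planted link the subject's mean empirical correlation varies with the
    subject random effect (subject_corr_sd) plus sampling noise of the Pearson
    estimate, var(r-hat) ~ (1 - rho^2)^2 / (T - 3), averaged over runs.
    """
    var = config.scale_noise_sd ** 2
    mu = {link: config.base_corr + config.delta_r for link in config.planted_links}
    for link, w in config.scale_weights.items():
        rho = mu[link]
        samp = (1.0 - rho ** 2) ** 2 / max(config.T - 3, 1) / config.runs_per_subject
        var += w ** 2 * (config.subject_corr_sd ** 2 + samp)
    return float(np.sqrt(var))


def generate_scales(
    link_weights: dict[tuple[int, int], float],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Integer 0-5 symptom scores for one patient.

    ``link_weights`` maps each planted link to the subject's mean link weight
    across runs. The latent score is centred at the patient-group expectation
    and binned into 6 equal-width levels over +/- 3 theoretical SDs, so the
    mapping is monotone in the latent and a zero latent falls at the 2/3 bin
    boundary (score 3). A degenerate (zero-width) latent maps every patient to
    the mid-range score 3.
    """
    mu = config.base_corr + config.delta_r
    systematic = sum(
        w * (link_weights[link] - mu) for link, w in config.scale_weights.items()
    )
    half_range = 3.0 * _scale_theoretical_sd(config)
    scores: dict[str, int] = {}
    for name in config.scale_names:
        z = systematic + (rng.normal(0.0, config.scale_noise_sd) if config.scale_noise_sd > 0 else 0.0)
        if half_range == 0.0:
            scores[name] = 3
        else:
            b = int(np.floor((z + half_range) / (2.0 * half_range) * 6.0))
            scores[name] = int(np.clip(b, 0, 5))
    return scores


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------

def _site_distortions(config: SyntheticConfig, site_ss: np.random.SeedSequence, n_vox: int):
    rng = np.random.default_rng(site_ss)
    offset = rng.normal(0.0, config.site_offset_sd, size=n_vox)
    scale = np.exp(rng.normal(0.0, config.site_scale_sd, size=n_vox))
    return offset, scale


def iter_cohort(config: SyntheticConfig) -> Iterator[tuple[CohortSample, RunTimeSeries]]:
    """Yield (sample, run) pairs one at a time; memory stays per-subject."""
    root = np.random.SeedSequence(config.seed)
    site_seeds = root.spawn(config.n_sites)
    subj_root = root.spawn(1)[0]
    subj_seeds = iter(subj_root.spawn(config.n_subjects))
    n_vox = int(np.prod(config.grid_dims))
    for s in range(config.n_sites):
        site_id = f"site{s + 1:02d}"
        offset, scale = _site_distortions(config, site_seeds[s], n_vox)
        roster = [(PATIENT, k) for k in range(config.patient_counts[s])]
        roster += [(CONTROL, k) for k in range(config.control_counts[s])]
        for group, k in roster:
            rng = np.random.default_rng(next(subj_seeds))
            tag = "P" if group == PATIENT else "C"
            subject_id = f"sub-{s + 1:02d}{tag}{k + 1:02d}"
            cov = _subject_cov(config, group, rng)
            latents = [
                simulate_gaussian_series(cov, config.T, rng)
                for _ in range(config.runs_per_subject)
            ]
            if group == PATIENT:
                lw = {}
                for i, j in config.planted_links:
                    rs = [np.corrcoef(lat[i], lat[j])[0, 1] for lat in latents]
                    lw[(i, j)] = float(np.mean(rs))
                scales = generate_scales(lw, config, rng)
            else:
                scales = {name: None for name in config.scale_names}
            for r, latent in enumerate(latents):
                run = generate_run(
                    config, cov, rng, site_offset=offset, site_scale=scale, latent=latent
                )
                sample = CohortSample(
                    subject_id=subject_id,
                    run_id=r + 1,
                    site_id=site_id,
                    group=group,
                    scales=dict(scales),
                )
                yield sample, run


def generate_cohort(config: SyntheticConfig) -> tuple[list[CohortSample], list[RunTimeSeries]]:
    """Materialize the full cohort: n_subjects x runs_per_subject samples."""
    samples, runs = [], []
    for sample, run in iter_cohort(config):
        samples.append(sample)
        runs.append(run)
    return samples, runs


# ---------------------------------------------------------------------------
# on-disk representation (TSV metadata + one 4-D NIfTI per run)
# ---------------------------------------------------------------------------

def samples_to_frame(samples: Sequence[CohortSample]):
    import pandas as pd

    scale_names = sorted({n for s in samples for n in s.scales}, key=lambda x: (len(x), x))
    rows = []
    for s in samples:
        row = {
            "subject_id": s.subject_id,
            "run_id": s.run_id,
            "site_id": s.site_id,
            "group": s.group,
        }
        for name in scale_names:
            v = s.scales.get(name)
            row[name] = "n/a" if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_samples(df) -> list[CohortSample]:
    scale_cols = [c for c in df.columns if c.startswith("scale_")]
    samples = []
    for _, row in df.iterrows():
        scales = {}
        for c in scale_cols:
            v = row[c]
            scales[c] = None if (str(v) == "n/a" or v != v) else int(v)
        samples.append(
            CohortSample(
                subject_id=str(row["subject_id"]),
                run_id=int(row["run_id"]),
                site_id=str(row["site_id"]),
                group=str(row["group"]),
                scales=scales,
            )
        )
    return samples


def _run_filename(sample: CohortSample) -> str:
    return f"{sample.subject_id}_run-{sample.run_id}.nii.gz"


def write_cohort(out_dir, samples, runs, config: SyntheticConfig | None = None) -> None:
    """Write metadata TSV, per-run 4-D NIfTI volumes, the mask, and a manifest."""
    import pathlib

    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples_to_frame(samples).to_csv(out / "participants.tsv", sep="\t", index=False)
    affine = np.eye(4)
    mask = runs[0].mask
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), out / "mask.nii.gz")
    for sample, run in zip(samples, runs):
        vol = np.zeros(mask.shape + (run.T,), dtype=np.float32)
        vol[tuple(run.node_coords.T)] = run.series
        nib.save(nib.Nifti1Image(vol, affine), out / _run_filename(sample))
    manifest = {"n_samples": len(samples), "grid_dims": list(mask.shape)}
    if config is not None:
        manifest["config"] = config_to_dict(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_cohort(in_dir) -> tuple[list[CohortSample], list[RunTimeSeries]]:
    import pathlib

    import nibabel as nib
    import pandas as pd

    src = pathlib.Path(in_dir)
    df = pd.read_csv(src / "participants.tsv", sep="\t")
    samples = frame_to_samples(df)
    mask = np.asarray(nib.load(src / "mask.nii.gz").dataobj).astype(bool)
    coords = np.argwhere(mask)
    runs = []
    for sample in samples:
        vol = np.asarray(nib.load(src / _run_filename(sample)).dataobj, dtype=float)
        runs.append(RunTimeSeries(node_coords=coords, series=vol[tuple(coords.T)], mask=mask))
    return samples, runs


def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_links"] = [list(l) for l in config.planted_links]
    d["scale_weights"] = {f"{i}-{j}": w for (i, j), w in config.scale_weights.items()}
    d["grid_dims"] = list(config.grid_dims)
    d["block_dims"] = list(config.block_dims)
    d["patients_per_site"] = list(config.patient_counts)
    d["controls_per_site"] = list(config.control_counts)
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    if "scale_weights" in d:
        d["scale_weights"] = {
            tuple(int(x) for x in k.split("-")): float(v) for k, v in d["scale_weights"].items()
        }
    if "planted_links" in d:
        d["planted_links"] = tuple(tuple(l) for l in d["planted_links"])
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
    return SyntheticConfig(**d)
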