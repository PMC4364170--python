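"""Synthetic two-group resting-state cohorts with known network structure.

The generator emulates the study design the analysis expects: a cortical
label atlas whose network territories have homotopic counterparts in a
cerebellar slab (the planted canonical map), white-matter and CSF
compartments with their own latent nuisance series, per-subject 4D BOLD in
which every network's cortical and cerebellar territories share a latent
band-limited (0.01-0.08 Hz) time course scaled by a per-subject coupling,
AR(1) voxel noise, slow drift and a high-frequency cardio-like sinusoid,
random-walk rigid-body motion traces, and a phenotype table (age, sex,
chlorpromazine-equivalent dose, scanner-upgrade flag, five symptom scales
with patient-only missingness).

Group differences are planted by giving a network different couplings in
the two groups; each subject's realized couplings are recorded as ground
truth so recovery can be scored exactly.  Latent signals are band-limited
so the planted connectivity survives the pipeline's band-pass.  Data are
generated already aligned on a common 2 mm grid: motion traces exist for
the nuisance design and QC, but no motion corruption/correction is
simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .preprocess import BoldSeries, MotionParams
from .seeds import LabelVolume, NETWORK_NAMES_17

N_DISCARD = 4           # volumes dropped at analysis time; simulated series include them
FIRST_LEVEL_COLUMNS = 10  # seed + wm + csf + 6 motion + intercept
LATENT_BAND_HZ = (0.01, 0.08)
NUISANCE_AMP = 1.0      # amplitude of the WM/CSF latent series in their compartments


@dataclass
class NetworkSpec:
    """One network: territory sizes (voxels) and per-group coupling."""

    network_id: int
    cortical_size: int
    cerebellar_size: int
    coupling_hc: float
    coupling_sz: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = NETWORK_NAMES_17.get(self.network_id, f"network {self.network_id}")
        for c in (self.coupling_hc, self.coupling_sz):
            if not (0.0 <= c <= 1.0):
                raise ValueError("couplings must lie in [0, 1]")
        if min(self.cortical_size, self.cerebellar_size) < 1:
            raise ValueError("territory sizes must be positive")


@dataclass
class SymptomScaleModel:
    """Generative model for one clinical scale among patients.

    score = mean + slope * (subject coupling - group coupling) + N(0, sd),
    clipped at zero.  ``network_id`` selects which network's coupling
    deviation drives the score; None averages over all networks.  The
    default slope of 0 makes the scale a pure null.
    """

    name: str
    mean: float
    sd: float
    slope: float = 0.0
    network_id: int | None = None


def default_symptom_models() -> list[SymptomScaleModel]:
    # means/SDs chosen to resemble a moderately symptomatic schizophrenia sample
    return [
        SymptomScaleModel("SAPS", 35.8, 19.1),
        SymptomScaleModel("SANS", 23.5, 15.9),
        SymptomScaleModel("YMRS", 14.7, 8.0),
        SymptomScaleModel("MADRS", 14.4, 9.3),
        SymptomScaleModel("PSYRATS_AH", 12.7, 14.3),
    ]


def positive_control_symptom_models(
    slope: float = 250.0, network_id: int = 7
) -> list[SymptomScaleModel]:
    """Symptom models with one planted coupling->score association.

    The first scale (SAPS) is driven by the chosen network's coupling
    deviation.  With the default subject coupling SD of 0.1, slope 250
    gives a true correlation of ~0.8 against the SAPS noise SD of 19.1 —
    comfortably detectable at the 0.05/35 Bonferroni threshold with ~30
    complete patient pairs (analytic power ~0.99).
    """
    models = default_symptom_models()
    models[0] = SymptomScaleModel("SAPS", 35.8, 19.1, slope=slope,
                                  network_id=network_id)
    return models


@dataclass
class CohortSpec:
    """Full generative description of a synthetic two-group cohort."""

    n_per_group: int = 12
    grid_shape: tuple[int, int, int] = (30, 30, 20)
    tr_seconds: float = 2.5
    n_volumes: int = 240
    networks: list[NetworkSpec] = field(default_factory=lambda: default_networks())
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    drift_amp: float = 1.0
    cardio_amp: float = 0.5
    cardio_freq_hz: float = 0.15
    # random-walk step SDs chosen so the Jenkinson mean absolute displacement
    # lands near the ~0.35 mm typical of a clinical resting-state sample
    motion_sd_mm: float = 0.15
    motion_sd_deg: float = 0.15
    coupling_subject_sd: float = 0.05
    symptom_models: list[SymptomScaleModel] = field(default_factory=default_symptom_models)
    missing_rate: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.ar1_phi) >= 1:
            raise ValueError("|ar1_phi| must be < 1")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0 < self.cardio_freq_hz < nyquist):
            raise ValueError(f"cardio frequency must be below Nyquist ({nyquist:.4g} Hz)")
        if self.n_volumes <= N_DISCARD + FIRST_LEVEL_COLUMNS:
            raise ValueError("n_volumes must exceed discard count + design rank")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must be in [0, 1]")
        if len({n.network_id for n in self.networks}) != len(self.networks):
            raise ValueError("duplicate network ids")


def default_networks() -> list[NetworkSpec]:
    """Ten-network roster emulating the retained study networks.

    The five association networks (ventral attention, salience, control A,
    control B, default mode A) are planted hypoconnected in the patient
    group; somatomotor A is planted hyperconnected; the rest have no group
    difference.
    """
    hypo = {7, 8, 12, 13, 16}
    hyper = {3}
    out = []
    for nid in (3, 4, 6, 7, 8, 9, 12, 13, 16, 17):
        hc = 0.6
        sz = 0.3 if nid in hypo else (0.8 if nid in hyper else 0.6)
        name = "limbic (9+10)" if nid == 9 else NETWORK_NAMES_17[nid]
        out.append(NetworkSpec(nid, cortical_size=150, cerebellar_size=120,
                               coupling_hc=hc, coupling_sz=sz, name=name))
    return out


def default_cohort_spec(**overrides) -> CohortSpec:
    """The default study-like synthetic cohort."""
    return CohortSpec(**overrides)


def seventeen_network_spec(rng_seed: int = 0) -> CohortSpec:
    """A 17-network atlas configuration for exercising seed selection.

    Six networks (visual peripheral/central, dorsal attention A, control C,
    auditory, default mode C) get minimal (<= 30 voxel) cerebellar
    territories, mirroring the exclusion roster of the canonical
    17-network cerebellar map.
    """
    minimal = {1, 2, 5, 11, 14, 15}
    nets = [
        NetworkSpec(nid, cortical_size=60,
                    cerebellar_size=12 if nid in minimal else 60,
                    coupling_hc=0.6, coupling_sz=0.6)
        for nid in range(1, 18)
    ]
    return CohortSpec(grid_shape=(34, 34, 22), networks=nets, rng_seed=rng_seed)


@dataclass
class AtlasBundle:
    """Label atlases and tissue masks on the common analysis grid."""

    cortical_labels: LabelVolume
    cerebellar_labels: LabelVolume
    cerebellum_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray

    def __post_init__(self) -> None:
        if set(self.cortical_labels.counts()) != set(self.cerebellar_labels.counts()):
            raise ValueError("cortical and cerebellar label sets disagree")
        pairs = [
            (self.cerebellum_mask, self.wm_mask),
            (self.cerebellum_mask, self.csf_mask),
            (self.wm_mask, self.csf_mask),
        ]
        if any((a & b).any() for a, b in pairs):
            raise ValueError("tissue masks must be pairwise disjoint")
        if ((self.cerebellar_labels.data > 0) & ~self.cerebellum_mask).any():
            raise ValueError("cerebellar labels must lie inside the cerebellum mask")

    def network_cerebellar_mask(self, network_id: int) -> np.ndarray:
        return self.cerebellar_labels.data == network_id


@dataclass
class SubjectRecord:
    """One subject's phenotype row plus ground-truth couplings."""

    subject_id: str
    group: str                  # "SZ" or "HC"
    age: float
    sex: str                    # "F" or "M"
    cpz: float                  # mg chlorpromazine-equivalent; NaN for HC
    scanner_flag: str           # "pre" or "post" upgrade
    scores: dict[str, float]    # scale -> value, NaN for missing
    true_coupling: dict[int, float]


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

def _zone_slices(nz: int):
    """z-extents of the cerebellum / WM / CSF / cortex slabs."""
    cb = max(2, round(0.3 * nz))
    wm = max(1, nz // 10)
    csf = max(1, nz // 10)
    if cb + wm + csf + 2 > nz:
        raise ValueError("grid too thin to hold all tissue slabs")
    return (0, cb), (cb, cb + wm), (cb + wm, cb + wm + csf), (cb + wm + csf, nz)


def _grow_territories(shape, z0, z1, sizes, rng) -> np.ndarray:
    """Grow compact labelled blobs inside the slab z in [z0, z1).

    Centers sit on a jittered in-plane lattice; each territory claims its
    requested number of nearest unclaimed voxels (ties broken
    lexicographically), so territories are compact and pairwise disjoint.
    """
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)
    ids = list(sizes)
    k = len(ids)
    m = int(np.ceil(np.sqrt(k)))
    order = rng.permutation(k)
    centers = {}
    for slot, idx in enumerate(order):
        gx, gy = divmod(slot, m)
        cx = (gx + 0.5) * nx / m + rng.integers(-1, 2)
        cy = (gy + 0.5) * ny / m + rng.integers(-1, 2)
        centers[ids[idx]] = (cx, cy, (z0 + z1 - 1) / 2.0)

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(z0, z1),
                             indexing="ij")
    coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    claimed = np.zeros(len(coords), dtype=bool)
    for nid in ids:
        size = sizes[nid]
        cx, cy, cz = centers[nid]
        d2 = ((coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
              + (coords[:, 2] - cz) ** 2)
        d2[claimed] = np.inf
        free = np.isfinite(d2).sum()
        if free < size:
            raise ValueError(
                f"territory {nid} ({size} voxels) does not fit: {free} voxels free"
            )
        pick = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))[:size]
        labels[coords[pick, 0], coords[pick, 1], coords[pick, 2]] = nid
        claimed[pick] = True
    return labels


def make_atlas(spec: CohortSpec) -> AtlasBundle:
    """Deterministic (seeded) atlas with homotopic cortical/cerebellar blobs."""
    rng = np.random.default_rng([int(spec.rng_seed), 101])
    shape = tuple(spec.grid_shape)
    (cb0, cb1), (wm0, wm1), (cs0, cs1), (cx0, cx1) = _zone_slices(shape[2])
    affine = np.diag([2.0, 2.0, 2.0, 1.0])

    names = {n.network_id: n.name for n in spec.networks}
    cort = _grow_territories(shape, cx0, cx1,
                             {n.network_id: n.cortical_size for n in spec.networks}, rng)
    cereb = _grow_territories(shape, cb0, cb1,
                              {n.network_id: n.cerebellar_size for n in spec.networks}, rng)

    cb_mask = np.zeros(shape, dtype=bool)
    cb_mask[:, :, cb0:cb1] = True
    wm_mask = np.zeros(shape, dtype=bool)
    wm_mask[:, :, wm0:wm1] = True
    csf_mask = np.zeros(shape, dtype=bool)
    csf_mask[:, :, cs0:cs1] = True

    return AtlasBundle(
        cortical_labels=LabelVolume(cort, affine, names),
        cerebellar_labels=LabelVolume(cereb, affine, names),
        cerebellum_mask=cb_mask,
        wm_mask=wm_mask,
        csf_mask=csf_mask,
    )


# ---------------------------------------------------------------------------
# Subject-level signal model
# ---------------------------------------------------------------------------

def _band_limited_latent(rng, n: int, tr: float, band=LATENT_BAND_HZ) -> np.ndarray:
    """Unit-variance Gaussian series restricted to the analysis band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=tr)
    keep = (f >= band[0]) & (f <= band[1])
    if not keep.any():
        raise ValueError("series too short to carry band-limited latents")
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return (x - x.mean()) / sd


def _ar1_noise(rng, shape, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with innovation SD ``sd``."""
    e = rng.standard_normal(shape) * sd
    if phi == 0.0:
        return e
    x0 = rng.standard_normal(shape[1:]) * sd / np.sqrt(1.0 - phi**2)
    zi = (phi * x0)[None, ...]
    out, _ = sp_signal.lfilter([1.0], [1.0, -phi], e, axis=0, zi=zi)
    return out


def simulate_subject(
    atlas: AtlasBundle, record: SubjectRecord, spec: CohortSpec, rng
) -> tuple[BoldSeries, MotionParams]:
    """Generate one subject's 4D BOLD series and motion trace.

    Every network's cortical and cerebellar voxels receive
    coupling * latent; WM/CSF voxels receive their compartment's latent;
    all voxels add AR(1) noise, slow drift (random per-voxel slope) and a
    cardio-like sinusoid with random per-voxel phase.
    """
    missing = [n.network_id for n in spec.networks
               if n.network_id not in record.true_coupling]
    if missing:
        raise ValueError(f"record lacks couplings for networks {missing}")
    shape = tuple(spec.grid_shape)
    nvox = int(np.prod(shape))
    t = spec.n_volumes
    tr = spec.tr_seconds

    data = _ar1_noise(rng, (t, nvox), spec.ar1_phi, spec.noise_sd) \
        if spec.noise_sd > 0 else np.zeros((t, nvox))

    flat_cort = atlas.cortical_labels.data.reshape(-1)
    flat_cereb = atlas.cerebellar_labels.data.reshape(-1)
    for net in spec.networks:
        latent = _band_limited_latent(rng, t, tr)
        members = (flat_cort == net.network_id) | (flat_cereb == net.network_id)
        data[:, members] += record.true_coupling[net.network_id] * latent[:, None]

    for mask in (atlas.wm_mask, atlas.csf_mask):
        latent = _band_limited_latent(rng, t, tr)
        data[:, mask.reshape(-1)] += NUISANCE_AMP * latent[:, None]

    if spec.drift_amp > 0:
        ramp = np.linspace(-1.0, 1.0, t)
        slopes = rng.standard_normal(nvox)
        data += spec.drift_amp * ramp[:, None] * slopes[None, :]
    if spec.cardio_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi, nvox)
        tt = np.arange(t) * tr
        data += spec.cardio_amp * np.sin(
            2.0 * np.pi * spec.cardio_freq_hz * tt[:, None] + phase[None, :]
        )

    steps = np.column_stack([
        rng.normal(0.0, np.deg2rad(spec.motion_sd_deg), (t, 3)).reshape(t, 3),
        rng.normal(0.0, spec.motion_sd_mm, (t, 3)).reshape(t, 3),
    ]) if (spec.motion_sd_deg > 0 or spec.motion_sd_mm > 0) else np.zeros((t, 6))
    motion = MotionParams(np.cumsum(steps, axis=0))

    bold = BoldSeries(np.moveaxis(data, 0, -1).reshape(*shape, t), tr)
    return bold, motion


# ---------------------------------------------------------------------------
# Cohort-level phenotype and I/O
# ---------------------------------------------------------------------------

def make_cohort_records(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw the phenotype table and per-subject ground-truth couplings."""
    rng = np.random.default_rng([int(spec.rng_seed), 202])
    records: list[SubjectRecord] = []
    for group, n in (("SZ", spec.n_per_group), ("HC", spec.n_per_group)):
        for i in range(n):
            age_mu, age_sd = (38.0, 10.0) if group == "SZ" else (39.0, 9.0)
            age = float(np.clip(rng.normal(age_mu, age_sd), 18, 65))
            sex = "F" if rng.random() < 0.40 else "M"
            scanner = "post" if rng.random() < 28 / 72 else "pre"
            cpz = float(max(0.0, rng.normal(580.0, 618.0))) if group == "SZ" else float("nan")
            coupling = {}
            for net in spec.networks:
                base = net.coupling_sz if group == "SZ" else net.coupling_hc
                coupling[net.network_id] = float(
                    np.clip(base + rng.normal(0.0, spec.coupling_subject_sd), 0.0, 1.0)
                )
            scores: dict[str, float] = {}
            for model in spec.symptom_models:
                if group == "HC":
                    scores[model.name] = float("nan")
                    continue
                if model.network_id is not None:
                    base = next(
                        n_.coupling_sz for n_ in spec.networks
                        if n_.network_id == model.network_id
                    )
                    dev = coupling[model.network_id] - base
                else:
                    devs = [
                        coupling[n_.network_id] - n_.coupling_sz for n_ in spec.networks
                    ]
                    dev = float(np.mean(devs))
                val = model.mean + model.slope * dev + rng.normal(0.0, model.sd)
                if rng.random() < spec.missing_rate:
                    val = float("nan")
                scores[model.name] = float(max(0.0, val)) if np.isfinite(val) else val
            records.append(SubjectRecord(
                subject_id=f"sub-{group}{i + 1:02d}", group=group, age=round(age, 1),
                sex=sex, cpz=cpz, scanner_flag=scanner, scores=scores,
                true_coupling=coupling,
            ))
    return records


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Phenotype DataFrame (one row per subject) from subject records."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "age": r.age,
               "sex": r.sex, "cpz": r.cpz, "scanner_flag": r.scanner_flag}
        row.update(r.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def subject_rng(spec: CohortSpec, subject_index: int) -> np.random.Generator:
    """Deterministic per-subject generator derived from the cohort seed."""
    return np.random.default_rng([int(spec.rng_seed), 303, int(subject_index)])


def simulate_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write a full synthetic cohort to disk; returns the manifest.

    Outputs: per-subject uncompressed NIfTI BOLD and 6-column whitespace
    motion files, atlas/mask NIfTIs, a phenotype TSV and a ground-truth
    JSON with every subject's realized couplings.  Identical specs produce
    byte-identical outputs.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = make_atlas(spec)
    records = make_cohort_records(spec)

    affine = atlas.cortical_labels.affine
    nib.save(atlas.cortical_labels.to_nifti(), out / "cortical_labels.nii")
    nib.save(atlas.cerebellar_labels.to_nifti(), out / "cerebellar_labels.nii")
    for name, mask in (("cerebellum_mask", atlas.cerebellum_mask),
                       ("wm_mask", atlas.wm_mask), ("csf_mask", atlas.csf_mask)):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), out / f"{name}.nii")

    manifest = {"subjects": [], "atlas": {
        "cortical_labels": "cortical_labels.nii",
        "cerebellar_labels": "cerebellar_labels.nii",
        "cerebellum_mask": "cerebellum_mask.nii",
        "wm_mask": "wm_mask.nii", "csf_mask": "csf_mask.nii",
    }}
    for i, rec in enumerate(records):
        bold, motion = simulate_subject(atlas, rec, spec, subject_rng(spec, i))
        bold_path = out / f"{rec.subject_id}_bold.nii"
        img = nib.Nifti1Image(bold.data.astype(np.float32), affine)
        img.header["pixdim"][4] = spec.tr_seconds
        nib.save(img, bold_path)
        par_path = out / f"{rec.subject_id}_motion.par"
        np.savetxt(par_path, motion.params, fmt="%.8f")
        manifest["subjects"].append({
            "subject_id": rec.subject_id,
            "bold": bold_path.name, "motion": par_path.name,
        })

    pheno = records_to_frame(records)
    pheno.to_csv(out / "participants.tsv", sep="\t", index=False, na_rep="")
    manifest["phenotype"] = "participants.tsv"

    truth = {
        "spec": _spec_to_jsonable(spec),
        "couplings": {r.subject_id: {str(k): v for k, v in r.true_coupling.items()}
                      for r in records},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest["ground_truth"] = "ground_truth.json"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["grid_shape"] = list(d["grid_shape"])
    return d
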