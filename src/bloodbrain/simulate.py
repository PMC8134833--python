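"""Synthetic paired blood/brain methylation cohorts with known ground truth.

Generative model, per individual *i* and trait *k*:

* latent trait value ``T_ik ~ N(0, 1)``;
* blood epigenetic factor ``S_ik = lambda_k * T_ik + sqrt(1-lambda_k^2) * e``;
* brain-region factor ``S_ikr = rho_kr * S_ik + sqrt(1-rho_kr^2) * e_r``
  (optionally with a noise component shared across regions so that the
  inter-region correlation can be targeted independently of the
  blood-region coupling);
* per-CpG M-values ``m_ijr = mu_j + c * w_j * S_ikr + sigma_cpg * e``
  with bimodal per-probe baselines ``mu_j``, transformed to beta values
  ``2^m / (2^m + 1)`` and clamped to [0.001, 0.999].

Effects are generated on the M-value (logit) scale so betas stay bounded;
the emitted matrices are betas, which is what the analyses consume. CpG
loadings are proportional to the fixture weights, making the projected
score the sufficient statistic of the latent factor: the pipeline's
estimated blood-brain score correlation converges to ``rho_kr``.

QC-failure artefacts (failing samples, low-beadcount probes, undetected
probes, sex mislabels) are planted on request and recorded in the ground
truth so filter sensitivity can be measured exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bloodbrain.io import (
    BLOOD,
    BRAIN_REGIONS,
    TISSUES,
    TRAITS,
    BetaMatrix,
    SampleSheet,
    WeightTable,
    write_beta_matrix,
    write_sample_sheet,
    write_table,
    write_weight_table,
)
from bloodbrain.episcore import SMOKING_CPG
from bloodbrain.phenotypes import CURRENT, FORMER, NEVER, PhenotypeRecord, records_to_table

logger = logging.getLogger(__name__)

_DEFAULT_RHO = {"BA17": 0.35, "BA20/21": 0.45, "BA24": 0.30, "BA35": 0.35, "BA46": 0.55}


@dataclass
class QcPlant:
    """Counts of QC failures to plant (brain failures go into ``tissue``)."""

    n_bad_samples: int = 0            # brain samples with a high det-p fraction
    n_bad_beadcount_probes: int = 0   # brain probes with beadcount < 3 in >5% of samples
    n_bad_detp_probes: int = 0        # brain probes with det-p > 0.05 in >1% of samples
    n_blood_bad_probes: int = 0       # blood probes detected in < 95% of samples
    n_sex_mislabels: int = 0          # samples whose recorded sex is flipped
    tissue: str = "BA17"


@dataclass
class SimulationConfig:
    """Configuration of a simulated cohort. ``seed`` is mandatory: all
    randomness flows from a single generator."""

    seed: int
    n_individuals: int = 14
    regions: tuple[str, ...] = TISSUES  # blood + 5 Brodmann areas
    traits: tuple[str, ...] = TRAITS
    n_cpgs_per_trait: int = 25
    rho_region: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RHO))
    rho_interregion: float | None = None
    lambda_trait: dict[str, float] = field(default_factory=lambda: {t: 0.7 for t in TRAITS})
    sigma_cpg: float = 0.2
    effect_scale: float = 0.5
    n_background_cpgs: int = 20
    n_x_probes: int = 10
    missing_ba35: bool = True
    n_female: int = 5
    n_never_smokers: int = 2
    n_current_smokers: int = 5
    n_missing_cigarettes: int = 5
    n_missing_start_age: int = 1
    qc_plant: QcPlant = field(default_factory=QcPlant)

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.n_cpgs_per_trait < 1:
            raise ValueError("n_cpgs_per_trait must be >= 1")
        brain = [r for r in self.regions if r != BLOOD]
        missing_rho = [r for r in brain if r not in self.rho_region]
        if missing_rho:
            raise ValueError(f"regions without a rho_region entry: {missing_rho}")
        for r, v in self.rho_region.items():
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"rho_region[{r}]={v} outside [-1, 1]")
        for t in self.traits:
            if t not in self.lambda_trait:
                raise ValueError(f"trait {t!r} has no lambda_trait entry")
        if self.n_never_smokers + self.n_current_smokers > self.n_individuals:
            raise ValueError("smoking group sizes exceed cohort size")

    @property
    def brain_regions(self) -> list[str]:
        return [r for r in self.regions if r != BLOOD]


@dataclass
class GroundTruth:
    """Everything needed to verify pipeline estimates against the generator."""

    latent: pd.DataFrame                       # individuals x traits
    factors: dict[str, pd.DataFrame]           # trait -> individuals x tissues
    rho_region: dict[str, float]
    lambda_trait: dict[str, float]
    true_sex: dict[str, str]
    planted_bad_samples: list[str] = field(default_factory=list)
    planted_bad_beadcount_probes: list[str] = field(default_factory=list)
    planted_bad_detp_probes: list[str] = field(default_factory=list)
    planted_blood_bad_probes: list[str] = field(default_factory=list)
    sex_mislabeled_samples: list[str] = field(default_factory=list)
    missing_ba35_individual: str | None = None


@dataclass
class SimulatedCohort:
    matrices: dict[str, BetaMatrix]           # tissue -> BetaMatrix
    sheet: SampleSheet
    phenotypes: pd.DataFrame
    records: list[PhenotypeRecord]
    weights: dict[str, WeightTable]
    truth: GroundTruth


def make_weight_fixture(trait: str, n_cpgs: int, seed: int) -> WeightTable:
    """Reproducible signed weight table: a sign-balanced mixture of small
    and large coefficients. The smoking fixture always contains cg05575921
    with a large negative weight (the site is hypomethylated in smokers)."""
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    rng = np.random.default_rng(seed)
    nums = rng.choice(99_999_999, size=n_cpgs, replace=False) + 1
    probes = [f"cg{n:08d}" for n in nums]
    large = rng.random(n_cpgs) < 0.2
    mags = np.where(large, np.abs(rng.normal(0.8, 0.2, n_cpgs)), np.abs(rng.normal(0.2, 0.08, n_cpgs)))
    signs = np.ones(n_cpgs)
    signs[: n_cpgs // 2] = -1.0
    rng.shuffle(signs)
    weights = mags * signs
    if trait == "smoking":
        probes[0] = SMOKING_CPG
        weights[0] = -abs(rng.normal(1.0, 0.1))
    return WeightTable(trait=trait, weights=pd.Series(weights, index=pd.Index(probes, name="probe_id")))


def _beta_from_m(m: np.ndarray) -> np.ndarray:
    beta = np.exp2(m) / (np.exp2(m) + 1.0)
    return np.clip(beta, 0.001, 0.999)


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate matched blood/brain beta matrices, sample sheet, phenotype
    records and ground truth under the factor model described above."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    individuals = [f"I{i + 1:03d}" for i in range(n)]
    brain_regions = cfg.brain_regions

    # --- sexes
    sexes = np.array(["F"] * cfg.n_female + ["M"] * (n - cfg.n_female))
    rng.shuffle(sexes)
    true_sex = {ind: str(s) for ind, s in zip(individuals, sexes)}

    # --- weight tables (disjoint probe sets across traits)
    weights: dict[str, WeightTable] = {}
    seen: set[str] = set()
    for trait in cfg.traits:
        for attempt in range(20):
            wt = make_weight_fixture(trait, cfg.n_cpgs_per_trait, int(rng.integers(2**31)))
            if not (set(wt.probe_ids) & seen):
                break
        else:  # pragma: no cover - 20 collisions in a 1e8 id space
            raise RuntimeError("could not draw disjoint weight fixtures")
        weights[trait] = wt
        seen |= set(wt.probe_ids)

    # --- latent traits and tissue factors
    latent = pd.DataFrame(rng.standard_normal((n, len(cfg.traits))), index=individuals, columns=list(cfg.traits))
    factors: dict[str, pd.DataFrame] = {}
    shared_frac = _shared_noise_fraction(cfg)
    for trait in cfg.traits:
        lam = cfg.lambda_trait[trait]
        s_blood = lam * latent[trait].to_numpy() + math.sqrt(1 - lam**2) * rng.standard_normal(n)
        cols = {BLOOD: s_blood}
        eta = rng.standard_normal(n)  # noise shared across regions
        for region in brain_regions:
            rho = cfg.rho_region[region]
            noise = math.sqrt(shared_frac) * eta + math.sqrt(1 - shared_frac) * rng.standard_normal(n)
            cols[region] = rho * s_blood + math.sqrt(1 - rho**2) * noise
        factors[trait] = pd.DataFrame(cols, index=individuals)

    # --- probe universe and baselines
    probe_ids: list[str] = []
    loadings: list[float] = []
    probe_trait: list[str | None] = []
    for trait in cfg.traits:
        wt = weights[trait]
        probe_ids += wt.probe_ids
        loadings += list(wt.weights.to_numpy())
        probe_trait += [trait] * len(wt)
    bg = [f"bg{i:06d}" for i in range(cfg.n_background_cpgs)]
    probe_ids += bg
    loadings += [0.0] * len(bg)
    probe_trait += [None] * len(bg)
    x_probes = [f"chrX{i:04d}" for i in range(cfg.n_x_probes)]

    n_autosomal = len(probe_ids)
    # bimodal baselines: half hypomethylated, half hypermethylated on M scale
    lowhigh = rng.random(n_autosomal) < 0.5
    mu = np.where(lowhigh, rng.uniform(-3.0, -1.0, n_autosomal), rng.uniform(1.0, 3.0, n_autosomal))
    loadings_arr = np.asarray(loadings)

    # --- sample sheet
    missing_ind: str | None = None
    if cfg.missing_ba35 and "BA35" in brain_regions:
        missing_ind = individuals[int(rng.integers(n))]
    rows = []
    for ind in individuals:
        for tissue in cfg.regions:
            if tissue == "BA35" and ind == missing_ind:
                continue
            sid = f"{ind}_{tissue.replace('/', '-')}"
            rows.append({"sample_id": sid, "individual_id": ind, "tissue": tissue, "recorded_sex": true_sex[ind]})
    sheet_frame = pd.DataFrame(rows)

    # --- per-tissue matrices
    matrices: dict[str, BetaMatrix] = {}
    for tissue in cfg.regions:
        tissue_rows = sheet_frame[sheet_frame["tissue"] == tissue]
        inds = list(tissue_rows["individual_id"])
        sids = list(tissue_rows["sample_id"])
        k = len(inds)

        s = np.zeros((n_autosomal, k))
        for t_idx, trait in enumerate(cfg.traits):
            mask = np.array([pt == trait for pt in probe_trait])
            fac = factors[trait].loc[inds, tissue].to_numpy()
            s[mask] = fac[None, :].repeat(mask.sum(), axis=0)
        m = mu[:, None] + cfg.effect_scale * loadings_arr[:, None] * s
        if cfg.sigma_cpg > 0:
            m = m + cfg.sigma_cpg * rng.standard_normal((n_autosomal, k))
        beta = _beta_from_m(m)

        x_mean = np.array([0.45 if true_sex[i] == "F" else 0.25 for i in inds])
        x_beta = np.clip(x_mean[None, :] + 0.02 * rng.standard_normal((cfg.n_x_probes, k)), 0.001, 0.999)

        all_probes = probe_ids + x_probes
        values = pd.DataFrame(np.vstack([beta, x_beta]), index=pd.Index(all_probes, name="probe_id"), columns=sids)
        detp = pd.DataFrame(rng.uniform(0.0, 1e-4, values.shape), index=values.index, columns=values.columns)
        bead = pd.DataFrame(
            5 + rng.poisson(2.0, values.shape).astype(float), index=values.index, columns=values.columns
        )
        platform = "450K" if tissue == BLOOD else "EPIC"
        matrices[tissue] = BetaMatrix(values=values, detection_p=detp, beadcount=bead, platform=platform)

    truth = GroundTruth(
        latent=latent,
        factors=factors,
        rho_region={r: cfg.rho_region[r] for r in brain_regions},
        lambda_trait=dict(cfg.lambda_trait),
        true_sex=true_sex,
        missing_ba35_individual=missing_ind,
    )

    _plant_qc_failures(cfg, matrices, sheet_frame, truth, rng)
    records = _simulate_phenotypes(cfg, latent, rng, individuals)

    sheet = SampleSheet(frame=sheet_frame)
    phenotypes = records_to_table(records)
    return SimulatedCohort(
        matrices=matrices, sheet=sheet, phenotypes=phenotypes, records=records, weights=weights, truth=truth
    )


def _shared_noise_fraction(cfg: SimulationConfig) -> float:
    """Fraction of region noise shared across regions needed to hit the
    requested inter-region correlation (0 when no target is set).

    With exchangeable rho the inter-region correlation is
    rho^2 + (1 - rho^2) * a, solved here for a."""
    if cfg.rho_interregion is None:
        return 0.0
    rhos = {cfg.rho_region[r] for r in cfg.brain_regions}
    if len(rhos) != 1:
        raise ValueError("rho_interregion targeting requires exchangeable (equal) rho_region values")
    rho = rhos.pop()
    denom = 1.0 - rho**2
    if denom <= 0:
        raise ValueError("rho_interregion cannot be targeted when rho_region = 1")
    a = (cfg.rho_interregion - rho**2) / denom
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"rho_interregion={cfg.rho_interregion} unreachable with rho_region={rho}")
    return a


def _plant_qc_failures(
    cfg: SimulationConfig,
    matrices: dict[str, BetaMatrix],
    sheet_frame: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> None:
    plant = cfg.qc_plant
    if plant.n_bad_samples or plant.n_bad_beadcount_probes or plant.n_bad_detp_probes:
        tissue = plant.tissue
        if tissue not in matrices or tissue == BLOOD:
            raise ValueError(f"qc_plant.tissue {tissue!r} is not a simulated brain region")
        m = matrices[tissue]
        detp = m.detection_p.copy()
        bead = m.beadcount.copy()
        n_probes, n_samples = m.shape
        samples = list(m.sample_ids)
        probes = list(m.probe_ids)

        order = rng.permutation(n_samples)
        bad_sample_idx = list(order[: plant.n_bad_samples])
        victim_pool = [j for j in order if j not in bad_sample_idx]

        # failing samples: >1% of probes at det-p > 0.05 (2% planted)
        n_bad_cells = max(2, math.ceil(0.02 * n_probes))
        for j in bad_sample_idx:
            rows = rng.choice(n_probes, size=n_bad_cells, replace=False)
            detp.iloc[rows, j] = rng.uniform(0.06, 1.0, n_bad_cells)
            truth.planted_bad_samples.append(samples[j])

        # low-beadcount probes: beadcount < 3 in >5% of samples (planted in ~6%+)
        n_low = max(1, math.ceil(0.06 * n_samples))
        probe_order = rng.permutation(n_probes)
        bead_probe_idx = probe_order[: plant.n_bad_beadcount_probes]
        for i in bead_probe_idx:
            cols = rng.choice(n_samples, size=n_low, replace=False)
            bead.iloc[i, cols] = 2.0
            truth.planted_bad_beadcount_probes.append(probes[i])

        # undetected probes: det-p > 0.05 in >1% of samples; each planted
        # probe fails on a distinct clean sample so no sample rule trips
        detp_probe_idx = probe_order[plant.n_bad_beadcount_probes: plant.n_bad_beadcount_probes + plant.n_bad_detp_probes]
        if len(detp_probe_idx) > len(victim_pool):
            raise ValueError("too many planted det-p probes for the number of clean samples")
        # 1/n_probes must stay at or below the sample rule threshold
        if n_probes < 100:
            raise ValueError("need >= 100 probes to plant probe failures without sample collateral")
        for i, j in zip(detp_probe_idx, victim_pool):
            detp.iloc[i, j] = 0.2
            truth.planted_bad_detp_probes.append(probes[i])

        matrices[tissue] = BetaMatrix(values=m.values, detection_p=detp, beadcount=bead, platform=m.platform)

    if plant.n_blood_bad_probes:
        m = matrices[BLOOD]
        detp = m.detection_p.copy()
        n_probes, n_samples = m.shape
        n_undet = max(1, math.ceil(0.06 * n_samples))  # detection rate < 95%
        probe_idx = rng.permutation(n_probes)[: plant.n_blood_bad_probes]
        for i in probe_idx:
            cols = rng.choice(n_samples, size=n_undet, replace=False)
            detp.iloc[i, cols] = 0.5
            truth.planted_blood_bad_probes.append(m.probe_ids[i])
        matrices[BLOOD] = BetaMatrix(values=m.values, detection_p=detp, beadcount=m.beadcount, platform=m.platform)

    if plant.n_sex_mislabels:
        idx = rng.permutation(len(sheet_frame))[: plant.n_sex_mislabels]
        for i in idx:
            cur = sheet_frame.iloc[i]["recorded_sex"]
            sheet_frame.iloc[i, sheet_frame.columns.get_loc("recorded_sex")] = "M" if cur == "F" else "F"
            truth.sex_mislabeled_samples.append(sheet_frame.iloc[i]["sample_id"])


def _simulate_phenotypes(
    cfg: SimulationConfig,
    latent: pd.DataFrame,
    rng: np.random.Generator,
    individuals: list[str],
) -> list[PhenotypeRecord]:
    n = cfg.n_individuals
    t_smoke = latent["smoking"].to_numpy() if "smoking" in latent.columns else np.zeros(n)
    t_alc = latent["alcohol"].to_numpy() if "alcohol" in latent.columns else np.zeros(n)
    t_bmi = latent["BMI"].to_numpy() if "BMI" in latent.columns else np.zeros(n)
    t_hdl = latent["HDL"].to_numpy() if "HDL" in latent.columns else np.zeros(n)

    # status tracks the smoking latent: heaviest exposure -> current smokers
    order = np.argsort(-t_smoke)
    status = np.full(n, FORMER)
    status[order[: cfg.n_current_smokers]] = CURRENT
    status[order[n - cfg.n_never_smokers:] if cfg.n_never_smokers else []] = NEVER

    age_at_assessment = rng.normal(77.9, 1.7, n)
    ever = [i for i in range(n) if status[i] != NEVER]
    missing_cigs = set(rng.permutation(ever)[: min(cfg.n_missing_cigarettes, len(ever))])
    with_cigs = [i for i in ever if i not in missing_cigs]
    missing_start = set(rng.permutation(with_cigs)[: min(cfg.n_missing_start_age, len(with_cigs))])

    records = []
    for i, ind in enumerate(individuals):
        st = int(status[i])
        cigs = start = stop = None
        if st != NEVER:
            cigs = None if i in missing_cigs else float(np.clip(12 + 6 * t_smoke[i] + rng.normal(0, 2), 1, 60))
            start = None if i in missing_start else float(np.clip(rng.normal(16, 2), 10, 25))
            stop = float(age_at_assessment[i]) if st == CURRENT else float(rng.uniform(45, 70))
        records.append(
            PhenotypeRecord(
                individual_id=ind,
                smoking_status=st,
                cigarettes_per_day=cigs,
                age_started_smoking=start,
                age_stopped_or_current=stop,
                alcohol_units_week=float(max(0.0, 11 + 6 * t_alc[i] + rng.normal(0, 3))),
                bmi=float(np.clip(25.5 + 4 * t_bmi[i] + rng.normal(0, 1.5), 15, 45)),
                hdl=float(np.clip(1.49 + 0.35 * t_hdl[i] + rng.normal(0, 0.1), 0.4, 3.0)),
            )
        )
    return records


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the simulated dataset as plain TSV/YAML under ``outdir``."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tissue, m in cohort.matrices.items():
        slug = tissue.replace("/", "-")
        write_beta_matrix(
            m,
            outdir / f"beta_{slug}.tsv",
            detection_p_path=outdir / f"detp_{slug}.tsv",
            beadcount_path=outdir / f"beadcount_{slug}.tsv",
        )
    write_sample_sheet(cohort.sheet, outdir / "sample_sheet.tsv")
    write_table(cohort.phenotypes, outdir / "phenotypes.tsv", kind="phenotype_table")
    for trait, wt in cohort.weights.items():
        write_weight_table(wt, outdir / f"weights_{trait}.tsv")
    truth = cohort.truth
    payload = {
        "rho_region": {k: float(v) for k, v in truth.rho_region.items()},
        "lambda_trait": {k: float(v) for k, v in truth.lambda_trait.items()},
        "true_sex": truth.true_sex,
        "latent": {t: [float(x) for x in truth.latent[t]] for t in truth.latent.columns},
        "individuals": list(truth.latent.index),
        "planted_bad_samples": truth.planted_bad_samples,
        "planted_bad_beadcount_probes": truth.planted_bad_beadcount_probes,
        "planted_bad_detp_probes": truth.planted_bad_detp_probes,
        "planted_blood_bad_probes": truth.planted_blood_bad_probes,
        "sex_mislabeled_samples": truth.sex_mislabeled_samples,
        "missing_ba35_individual": truth.missing_ba35_individual,
    }
    with open(outdir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    logger.info("wrote simulated cohort to %s", outdir)
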