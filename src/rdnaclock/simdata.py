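"""Synthetic lobsters: CpG panels, bisulphite read counts and body sizes.

Generates data with the statistical structure the downstream analysis
assumes — per-locus linear methylation-age trajectories (clamped to
[0, 100]), negative-binomial read coverage, binomial methylation calls with
a bisulphite non-conversion error that inflates apparent methylation,
optional batch and sex offsets, and von Bertalanffy body sizes — so the
whole pipeline is testable without any external download.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .methylation import MethylCountTable, locus_sort_key, write_coverage_file

#: rDNA regions a simulated panel is spread over (5' -> 3')
PANEL_REGIONS = ("18S", "ITS1", "ITS2", "28S")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class LocusSpec:
    """One CpG's linear methylation-age trajectory.

    ``intercept_a`` is percent methylation at age 0, ``slope_b`` percent per
    month (0 for non-informative loci) and ``sd_individual`` the
    between-individual biological noise SD in percent.
    """

    locus_id: str
    region: str
    position: int
    intercept_a: float
    slope_b: float
    sd_individual: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.intercept_a <= 100.0:
            raise ConfigurationError(f"intercept_a must be in [0, 100], got {self.intercept_a}")
        if self.position < 1:
            raise ConfigurationError("position must be >= 1 (1-based)")
        if self.sd_individual < 0:
            raise ConfigurationError("sd_individual must be >= 0")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the seven known-age cohorts (ages in months, with the
    40/51-month cohorts sequenced in a second batch) plus a wild group of
    unknown age, a ~60% informative CpG panel, and the observed mean read
    coverages and >99% bisulphite conversion.
    """

    n_loci: int = 355
    frac_informative: float = 0.60
    cohort_ages_months: list[float] = field(
        default_factory=lambda: [0.0, 1.8, 7.3, 12.5, 24.8, 40.0, 51.0]
    )
    cohort_sizes: list[int] = field(default_factory=lambda: [27, 29, 26, 19, 32, 5, 17])
    batch2_cohorts: list[float] = field(default_factory=lambda: [40.0, 51.0])
    n_wild: int = 38
    wild_age_range_months: tuple[float, float] = (48.0, 108.0)
    coverage_mean: float = 7107.0
    coverage_mean_batch2: float = 25253.0
    coverage_dispersion: float = 10.0
    conversion_rate: float = 0.995
    missing_rate: float = 0.0
    batch_shift: float = 0.0
    sex_shift: float = 0.0
    sex_shift_signs: dict[float, int] = field(default_factory=dict)  # cohort age -> +-1
    sd_individual: float = 2.0
    age_jitter_months: float = 0.0
    slope_range: tuple[float, float] = (0.15, 1.2)
    intercept_range: tuple[float, float] = (5.0, 95.0)
    growth_params: tuple[float, float, float] = (46.2, 0.06, 3.288)  # (Linf mm, K /month, t0 months)
    cv_linf: float = 0.05
    sd_measure_mm: float = 1.0
    min_size_age_months: float = 7.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        for name in ("frac_informative", "conversion_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_mean <= 0 or self.coverage_mean_batch2 <= 0:
            raise ConfigurationError("coverage means must be > 0")
        if self.coverage_dispersion <= 0:
            raise ConfigurationError("coverage_dispersion must be > 0")
        if len(self.cohort_ages_months) != len(self.cohort_sizes):
            raise ConfigurationError("cohort_ages_months and cohort_sizes must have equal length")
        if any(a < 0 for a in self.cohort_ages_months):
            raise ConfigurationError("cohort ages must be >= 0")
        if self.wild_age_range_months[0] > self.wild_age_range_months[1]:
            raise ConfigurationError("wild_age_range_months must be an interval")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class TrueState:
    """Ground truth for parameter-recovery tests.

    ``true_age`` is months per sample (wild included); ``true_methylation``
    is the per-(sample, locus) percent before sequencing noise, after
    clamping and batch/sex offsets.
    """

    true_age: pd.Series
    sex: pd.Series
    batch: pd.Series
    true_methylation: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_age": {k: float(v) for k, v in self.true_age.items()},
            "sex": dict(self.sex.items()),
            "batch": {k: int(v) for k, v in self.batch.items()},
            "true_methylation": {
                sample: {locus: float(v) for locus, v in row.items()}
                for sample, row in self.true_methylation.iterrows()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def make_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[LocusSpec]:
    """Draw a CpG panel with exactly round(frac_informative * n_loci) sloped loci.

    Informative slopes are symmetric in sign (hyper- and hypomethylating loci
    both represented); everything is deterministic given the config seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_loci
    n_informative = int(round(config.frac_informative * n))

    # spread loci across the regions proportionally, unique positions per region
    region_idx = rng.integers(0, len(PANEL_REGIONS), size=n)
    positions_used: dict[str, set[int]] = {r: set() for r in PANEL_REGIONS}
    placements: list[tuple[str, int]] = []
    for ri in region_idx:
        region = PANEL_REGIONS[ri]
        while True:
            pos = int(rng.integers(1, 4000))
            if pos not in positions_used[region]:
                positions_used[region].add(pos)
                break
        placements.append((region, pos))

    informative = np.zeros(n, dtype=bool)
    informative[rng.permutation(n)[:n_informative]] = True
    lo, hi = config.slope_range
    magnitudes = rng.uniform(lo, hi, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    intercepts = rng.uniform(*config.intercept_range, size=n)

    panel = []
    for i, (region, pos) in enumerate(placements):
        slope = float(signs[i] * magnitudes[i]) if informative[i] else 0.0
        # keep hypomethylating loci from starting too low / hyper from too high
        a = float(intercepts[i])
        panel.append(
            LocusSpec(
                locus_id=f"{region}_{pos}",
                region=region,
                position=pos,
                intercept_a=a,
                slope_b=slope,
                sd_individual=config.sd_individual,
            )
        )
    panel.sort(key=lambda spec: locus_sort_key(spec.locus_id))
    return panel


def true_methylation(locus: LocusSpec, age: float, individual_offset: float = 0.0) -> float:
    """Linear trajectory clamped to [0, 100] (saturation behaviour)."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    value = locus.intercept_a + locus.slope_b * age + individual_offset
    return float(min(100.0, max(0.0, value)))


def make_samplesheet(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample metadata table: known-age cohorts plus unknown-age wild samples.

    Columns: sample_id, cohort, age_months (NaN for wild), true_age_months,
    tissue, sex, batch. Tissue is claw for young cohorts, leg for batch-2
    cohorts, antenna for wild.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    counter = 1
    for age, size in zip(config.cohort_ages_months, config.cohort_sizes):
        batch = 2 if age in config.batch2_cohorts else 1
        tissue = "leg" if batch == 2 else "claw"
        for _ in range(size):
            jitter = (
                rng.uniform(-config.age_jitter_months, config.age_jitter_months)
                if config.age_jitter_months > 0
                else 0.0
            )
            rows.append(
                {
                    "sample_id": f"L{counter:03d}",
                    "cohort": f"{age:g}",
                    "age_months": age,
                    "true_age_months": max(0.0, age + jitter),
                    "tissue": tissue,
                    "sex": str(rng.choice(["F", "M"])),
                    "batch": batch,
                }
            )
            counter += 1
    lo, hi = config.wild_age_range_months
    for _ in range(config.n_wild):
        rows.append(
            {
                "sample_id": f"W{counter:03d}",
                "cohort": "wild",
                "age_months": math.nan,
                "true_age_months": float(rng.uniform(lo, hi)),
                "tissue": "antenna",
                "sex": str(rng.choice(["F", "M"])),
                "batch": 1,
            }
        )
        counter += 1
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    panel: list[LocusSpec],
    samplesheet: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MethylCountTable, TrueState]:
    """Draw read counts per (sample, locus).

    Coverage is negative-binomial with the configured mean (batch-2 samples
    use ``coverage_mean_batch2``); methylated reads are
    Binomial(coverage, p_obs/100) with
    ``p_obs = p_true + (100 - p_true) * (1 - conversion_rate)`` — incomplete
    bisulphite conversion reads unmethylated C as methylated, inflating the
    apparent level. A ``missing_rate`` fraction of cells is withheld
    entirely; ``batch_shift`` and the cohort-signed sex offset move p_true
    before clamping.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = list(samplesheet.index)
    locus_ids = [spec.locus_id for spec in panel]
    n_s, n_l = len(samples), len(locus_ids)

    ages = samplesheet["true_age_months"].to_numpy(dtype=float)
    batches = samplesheet["batch"].to_numpy()
    is_female = (samplesheet["sex"] == "F").to_numpy()
    cohorts = samplesheet["cohort"].to_numpy()

    intercepts = np.array([s.intercept_a for s in panel])
    slopes = np.array([s.slope_b for s in panel])
    sd_ind = np.array([s.sd_individual for s in panel])

    offsets = rng.normal(0.0, 1.0, size=(n_s, n_l)) * sd_ind[None, :]
    p_true = intercepts[None, :] + slopes[None, :] * ages[:, None] + offsets
    p_true += np.where(batches[:, None] == 2, config.batch_shift, 0.0)
    if config.sex_shift != 0.0:
        sex_sign = np.array(
            [
                config.sex_shift_signs.get(float(c), 1) if c != "wild" else 1
                for c in cohorts
            ],
            dtype=float,
        )
        p_true += (is_female.astype(float) * sex_sign)[:, None] * config.sex_shift
    np.clip(p_true, 0.0, 100.0, out=p_true)

    p_obs = p_true + (100.0 - p_true) * (1.0 - config.conversion_rate)

    mean_cov = np.where(batches == 2, config.coverage_mean_batch2, config.coverage_mean)
    theta = config.coverage_dispersion
    if math.isinf(theta):
        coverage = rng.poisson(lam=np.broadcast_to(mean_cov[:, None], (n_s, n_l)))
    else:
        p_nb = theta / (theta + mean_cov)
        coverage = rng.negative_binomial(theta, np.broadcast_to(p_nb[:, None], (n_s, n_l)))
    meth = rng.binomial(coverage, p_obs / 100.0)

    withheld = rng.random((n_s, n_l)) < config.missing_rate
    missing = withheld | (coverage == 0)

    meth_f = meth.astype(float)
    unmeth_f = (coverage - meth).astype(float)
    meth_f[missing] = np.nan
    unmeth_f[missing] = np.nan

    loci = pd.DataFrame(
        {"region": [s.region for s in panel], "position": [s.position for s in panel]},
        index=pd.Index(locus_ids, name="locus_id"),
    )
    table = MethylCountTable(
        meth=pd.DataFrame(meth_f, index=samples, columns=locus_ids),
        unmeth=pd.DataFrame(unmeth_f, index=samples, columns=locus_ids),
        loci=loci,
    )
    truth = TrueState(
        true_age=samplesheet["true_age_months"].astype(float),
        sex=samplesheet["sex"],
        batch=samplesheet["batch"],
        true_methylation=pd.DataFrame(p_true, index=samples, columns=locus_ids),
    )
    return table, truth


def simulate_sizes(
    samplesheet: pd.DataFrame,
    growth_params: tuple[float, float, float],
    cv_linf: float = 0.0,
    sd_measure: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Carapace lengths from a von Bertalanffy curve with individual Linf.

    ``CL_i = Linf_i (1 - exp(-K (age_i - t0))) + eps`` with Linf_i lognormal
    around Linf at coefficient of variation ``cv_linf`` and measurement noise
    ``eps ~ N(0, sd_measure)``. Negative values are truncated at 0 (ages at
    or below t0 therefore clamp to 0).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    linf, k, t0 = growth_params
    ages = samplesheet["true_age_months"].to_numpy(dtype=float)
    if np.isnan(ages).any():
        raise ValueError("ages must be known for all samples")
    n = len(ages)
    if cv_linf > 0:
        sigma = math.sqrt(math.log(1.0 + cv_linf**2))
        mu = math.log(linf) - sigma**2 / 2.0
        linf_i = rng.lognormal(mu, sigma, size=n)
    else:
        linf_i = np.full(n, linf)
    eps = rng.normal(0.0, sd_measure, size=n) if sd_measure > 0 else np.zeros(n)
    sizes = linf_i * (1.0 - np.exp(-k * (ages - t0))) + eps
    sizes = np.maximum(sizes, 0.0)
    return pd.Series(sizes, index=samplesheet.index, name="carapace_length_mm")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[LocusSpec], pd.DataFrame, MethylCountTable, TrueState]:
    """Full draw: panel, samplesheet with sizes, counts and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = make_panel(config, rng=rng)
    sheet = make_samplesheet(config, rng=rng)
    table, truth = simulate_counts(panel, sheet, config, rng=rng)
    sizes = simulate_sizes(
        sheet, config.growth_params, cv_linf=config.cv_linf, sd_measure=config.sd_measure_mm, rng=rng
    )
    sheet = sheet.copy()
    sheet["carapace_length_mm"] = sizes.where(
        sheet["true_age_months"] >= config.min_size_age_months
    )
    return panel, sheet, table, truth


def write_dataset(
    outdir: str | Path,
    samplesheet: pd.DataFrame,
    table: MethylCountTable,
    truth: TrueState,
    panel: list[LocusSpec] | None = None,
) -> None:
    """Write per-sample coverage files, samples.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample in table.samples:
        mask = ~table.missing_mask().loc[sample]
        present = mask[mask].index
        frame = pd.DataFrame(
            {
                "region": table.loci.loc[present, "region"].to_numpy(),
                "position": table.loci.loc[present, "position"].to_numpy(),
                "count_meth": table.meth.loc[sample, present].astype(int).to_numpy(),
                "count_unmeth": table.unmeth.loc[sample, present].astype(int).to_numpy(),
            }
        )
        write_coverage_file(frame, outdir / f"{sample}.cov")
    out_sheet = samplesheet.reset_index()[
        [
            c
            for c in (
                "sample_id",
                "age_months",
                "tissue",
                "sex",
                "cohort",
                "batch",
                "carapace_length_mm",
            )
            if c in samplesheet.reset_index().columns
        ]
    ]
    out_sheet.to_csv(outdir / "samples.csv", index=False, float_format="%.10g")
    truth.to_json(outdir / "truth.json")
    if panel is not None:
        Path(outdir / "panel.json").write_text(
            json.dumps([asdict(spec) for spec in panel], indent=2) + "\n"
        )
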