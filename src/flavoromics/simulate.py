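"""Synthetic study generator: panel ratings, multi-period chemistry, genotypes.

The generator emulates the statistical structure of a multi-year fresh-fruit
sensory/chemical study:

* bounded consumer ratings with panelist random offsets and rating noise,
  sessions of a few samples each rated by their own panel;
* log-normal volatile abundances driven by latent pathway factors (giving
  correlated ester/aldehyde blocks), per-period batch offsets, and a
  detection mask with period-structural absences;
* sugar-driven sweetness plus a small set of planted volatile "enhancers"
  whose effects on sweetness and liking act on the standardized (batch-free)
  log abundance and are therefore independent of total sugars;
* an optional linear temperature trend on sweetness and liking;
* a separate genotyped population with one biallelic QTL explaining a
  configured fraction of a log-normal ester phenotype's variance.

Every draw flows from one seed through named substreams, so adding a
generator does not perturb the others and identical configs give bitwise
identical output.  A :class:`SimulationTruth` registry records the planted
parameters for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from flavoromics.containers import (
    ALL_ATTRIBUTES,
    ChemicalMatrix,
    GenotypeMatrix,
    PanelRatings,
    attribute_bounds,
)

SUGARS = ("glucose", "fructose", "sucrose")
ACIDS = ("citric_acid", "malic_acid")

# Rough composition of a cultivated-strawberry volatile panel.
_VOLATILE_CLASS_WEIGHTS = {
    "ester": 0.45,
    "aldehyde": 0.12,
    "ketone": 0.08,
    "alcohol": 0.08,
    "lactone": 0.05,
    "terpene": 0.07,
    "furan": 0.03,
    "other": 0.12,
}

# Substream labels (second word of the rng seed sequence).
_STREAM_TRUTH = 0
_STREAM_CHEM = 1
_STREAM_SENSORY = 2
_STREAM_GENO = 3


class InvalidConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Counts must be >= 1; all variance fractions lie in [0, 1) and the
    fractions contributing to one response must sum below 1.  The seed fully
    determines every generated table.
    """

    n_samples: int = 148
    n_panelists_per_session: int = 100
    samples_per_session: int = 4
    panelist_sd: float = 10.0
    rating_noise_sd: float = 15.0
    n_volatiles: int = 113
    n_common_volatiles: int = 59
    n_periods: int = 3
    batch_shift_sd: float = 0.5
    n_enhancers: int = 3
    enhancer_effect: float = 0.12
    sugar_effect: float = 0.40
    n_latent_pathways: int = 8
    n_markers: int = 50
    qtl_variance: float = 0.15
    allele_freq: float = 0.3
    n_genotyped: int = 300
    n_genotypes: int = 48
    replicates: int = 3
    sensory_total_sd: float = 18.0
    temperature_slope: float = 0.0
    sourness_effect: float = 0.30
    glucose_fructose_r: float = 0.91
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_panelists_per_session": self.n_panelists_per_session,
            "samples_per_session": self.samples_per_session,
            "n_volatiles": self.n_volatiles,
            "n_periods": self.n_periods,
            "n_latent_pathways": self.n_latent_pathways,
            "n_markers": self.n_markers,
            "n_genotyped": self.n_genotyped,
            "n_genotypes": self.n_genotypes,
            "replicates": self.replicates,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise InvalidConfigError(f"{name} must be a count >= 1, got {v}")
        if self.n_enhancers < 0:
            raise InvalidConfigError("n_enhancers must be >= 0")
        for name in ("panelist_sd", "rating_noise_sd", "batch_shift_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        for name in ("enhancer_effect", "sugar_effect", "qtl_variance",
                     "sourness_effect"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise InvalidConfigError(f"{name} must be in [0, 1), got {v}")
        total = self.sugar_effect + self.n_enhancers * self.enhancer_effect
        if total >= 1.0:
            raise InvalidConfigError(
                "sugar_effect + n_enhancers*enhancer_effect must be < 1, "
                f"got {total}"
            )
        if not (0.0 < self.allele_freq < 1.0):
            raise InvalidConfigError(
                f"allele_freq must be in (0, 1), got {self.allele_freq}"
            )
        if self.n_latent_pathways > self.n_volatiles:
            raise InvalidConfigError("n_latent_pathways > n_volatiles")
        if self.n_common_volatiles > self.n_volatiles:
            raise InvalidConfigError("n_common_volatiles > n_volatiles")
        if not (0.0 < abs(self.glucose_fructose_r) < 1.0):
            raise InvalidConfigError("glucose_fructose_r must be in (0, 1)")


@dataclass
class SimulationTruth:
    """Registry of planted parameters, for parameter-recovery tests."""

    compound_ids: list
    compound_class: dict
    common_volatiles: list
    enhancer_ids: list
    sweetness_slopes: dict       # compound -> rating units per SD of abundance
    liking_slopes: dict
    sugar_slope_sweetness: float
    sugar_slope_liking: float
    pathway_of: dict             # volatile -> latent pathway index
    pathway_loading: dict        # volatile -> loading on its pathway
    noise_sd: dict               # volatile -> residual log-abundance sd
    base_log: dict               # volatile -> mean log abundance
    period_offsets: dict         # period -> {compound -> log-unit offset}
    period_presence: dict        # volatile -> list of periods where present
    qtl_marker: str = "M001"
    qtl_variance: float = 0.15
    attribute_intercepts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)

    @classmethod
    def load(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _period_labels(config: SimConfig) -> list[str]:
    return [f"P{i + 1}" for i in range(config.n_periods)]


def make_truth(config: SimConfig) -> SimulationTruth:
    """Draw the planted parameters (not the sample-level data)."""
    config.validate()
    rng = _rng(config, _STREAM_TRUTH)
    periods = _period_labels(config)

    vol_ids = [f"V{i + 1:03d}" for i in range(config.n_volatiles)]
    classes = dict(zip(SUGARS, ["sugar"] * 3)) | dict(zip(ACIDS, ["acid"] * 2))
    names = list(_VOLATILE_CLASS_WEIGHTS)
    probs = np.array(list(_VOLATILE_CLASS_WEIGHTS.values()))
    classes |= dict(zip(vol_ids, rng.choice(names, config.n_volatiles, p=probs)))

    pathway_of = {v: int(rng.integers(config.n_latent_pathways)) for v in vol_ids}
    pathway_loading = {v: float(rng.uniform(0.6, 1.0)) for v in vol_ids}
    noise_sd = {v: float(rng.uniform(0.3, 0.6)) for v in vol_ids}
    base_log = {v: float(rng.normal(np.log(200.0), 1.2)) for v in vol_ids}

    common = list(rng.choice(vol_ids, config.n_common_volatiles, replace=False))
    common.sort()
    extras = [v for v in vol_ids if v not in common]
    period_presence = {v: periods for v in common}
    for v in extras:
        # present in a random proper subset of periods (possibly one)
        k = int(rng.integers(1, config.n_periods))
        period_presence[v] = sorted(rng.choice(periods, k, replace=False))

    # Enhancers come from the always-detected set and each gets a dedicated
    # latent factor: their sweetness effect is compound-specific rather than
    # a proxy for a whole pathway, so mutual correlations (and correlations
    # with pathway mates) stay near zero and each planted variance fraction
    # is realized to Monte-Carlo accuracy.
    n_enh = min(config.n_enhancers, len(common))
    enhancers = list(rng.choice(common, n_enh, replace=False))
    for i, v in enumerate(enhancers):
        pathway_of[v] = config.n_latent_pathways + i

    sigma = config.sensory_total_sd
    slope_enh = float(np.sqrt(config.enhancer_effect) * sigma)
    sweetness_slopes = {v: slope_enh for v in enhancers}
    # liking shares the enhancers; its sugar share is smaller, mirroring the
    # weaker sugars+acids baseline typically seen for hedonics.
    liking_slopes = {v: slope_enh for v in enhancers}
    sugar_slope_sweet = float(np.sqrt(config.sugar_effect) * sigma)
    sugar_slope_lik = float(np.sqrt(0.75 * config.sugar_effect) * sigma)

    offsets = {
        p: {c: float(rng.normal(0.0, config.batch_shift_sd)) for c in vol_ids}
        for p in periods
    }
    for p in periods:  # sugars/acids re-assayed per period too
        for c in (*SUGARS, *ACIDS):
            offsets[p][c] = float(rng.normal(0.0, config.batch_shift_sd / 2))

    return SimulationTruth(
        compound_ids=list(SUGARS) + list(ACIDS) + vol_ids,
        compound_class=classes,
        common_volatiles=common,
        enhancer_ids=enhancers,
        sweetness_slopes=sweetness_slopes,
        liking_slopes=liking_slopes,
        sugar_slope_sweetness=sugar_slope_sweet,
        sugar_slope_liking=sugar_slope_lik,
        pathway_of=pathway_of,
        pathway_loading=pathway_loading,
        noise_sd=noise_sd,
        base_log=base_log,
        period_offsets=offsets,
        period_presence=period_presence,
        qtl_marker=f"M{1:03d}",
        qtl_variance=config.qtl_variance,
        attribute_intercepts={
            "liking": 25.8,
            "texture_liking": 30.0,
            "sweetness": 40.0,
            "sourness": 30.0,
            "flavor_intensity": 45.0,
        },
    )


def _latent_chemistry(config: SimConfig, truth: SimulationTruth) -> dict:
    """Deterministic sample-level latent state shared by chemistry + sensory.

    Returns per-sample period/session/genotype/temperature assignments, the
    batch-free log-abundance matrix, its standardized version (the design
    the planted sensory effects act on), and the standardized log total
    sugars / total acids.
    """
    rng = _rng(config, _STREAM_CHEM)
    n = config.n_samples
    periods = _period_labels(config)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    # contiguous period blocks (harvest eras), near-equal sizes
    bounds = np.linspace(0, n, config.n_periods + 1).round().astype(int)
    period = np.empty(n, dtype=object)
    for i, p in enumerate(periods):
        period[bounds[i]:bounds[i + 1]] = p

    # sessions = harvest dates of a few samples each, within a period
    session = np.empty(n, dtype=object)
    temperature = np.empty(n)
    k = 0
    for i in range(0, n, config.samples_per_session):
        temp = rng.uniform(15.0, 25.0)
        for j in range(i, min(i + config.samples_per_session, n)):
            session[j] = f"D{k + 1:03d}"
            temperature[j] = temp
        k += 1
    genotype = np.array(
        [f"G{g + 1:02d}" for g in rng.integers(config.n_genotypes, size=n)]
    )

    factors = rng.standard_normal(
        (n, config.n_latent_pathways + config.n_enhancers)
    )
    vols = [c for c in truth.compound_ids if c not in SUGARS + ACIDS]
    log_clean = np.empty((n, len(vols)))
    for j, v in enumerate(vols):
        bio = truth.noise_sd[v] * rng.standard_normal(n)
        # technical noise shrinks through averaging over replicate measurements
        tech = 0.15 * rng.standard_normal((n, config.replicates)).mean(axis=1)
        log_clean[:, j] = (
            truth.base_log[v]
            + truth.pathway_loading[v] * factors[:, truth.pathway_of[v]]
            + bio
            + tech
        )

    # sugars: one shared factor; glucose/fructose noise tuned to the target r
    r = config.glucose_fructose_r
    gf_noise = np.sqrt(1.0 / r - 1.0)
    s_factor = rng.standard_normal(n)
    a_factor = rng.standard_normal(n)
    sug_log = {
        "glucose": np.log(2000.0) + 0.35 * (s_factor + gf_noise * rng.standard_normal(n)),
        "fructose": np.log(2200.0) + 0.35 * (s_factor + gf_noise * rng.standard_normal(n)),
        "sucrose": np.log(1500.0) + 0.45 * (s_factor + 0.8 * rng.standard_normal(n)),
    }
    acid_log = {
        "citric_acid": np.log(700.0) + 0.3 * (a_factor + 0.5 * rng.standard_normal(n)),
        "malic_acid": np.log(250.0) + 0.3 * (a_factor + 0.8 * rng.standard_normal(n)),
    }
    # the sweetness/liking sugar driver is the standardized mean of the log
    # sugar signals (a geometric-mean total): linear in the log
    # concentrations, so a regression on the measured sugars can recover the
    # planted variance fraction exactly
    log_total_sugars = sum(sug_log.values()) / 3.0
    log_total_acids = sum(acid_log.values()) / 2.0

    def z(x):
        return (x - x.mean()) / x.std(ddof=1)

    z_vol = np.apply_along_axis(z, 0, log_clean)
    return {
        "sample_ids": sample_ids,
        "period": period,
        "session": session,
        "temperature": temperature,
        "genotype": genotype,
        "volatile_ids": vols,
        "log_clean": log_clean,
        "z_volatiles": pd.DataFrame(z_vol, index=sample_ids, columns=vols),
        "sugar_log": sug_log,
        "acid_log": acid_log,
        "z_sugar": pd.Series(z(log_total_sugars), index=sample_ids),
        "z_acid": pd.Series(z(log_total_acids), index=sample_ids),
    }


def generate_chemical_matrix(config: SimConfig, truth: SimulationTruth) -> ChemicalMatrix:
    """Sample x compound abundances with period batch effects and detection mask."""
    config.validate()
    lat = _latent_chemistry(config, truth)
    n = config.n_samples
    vols = lat["volatile_ids"]
    log_ab = lat["log_clean"].copy()
    for j, v in enumerate(vols):
        for i in range(n):
            log_ab[i, j] += truth.period_offsets[lat["period"][i]][v]

    abundance = pd.DataFrame(
        np.exp(log_ab), index=lat["sample_ids"], columns=vols
    )
    # structural absences: compound missing in every sample of an absent period
    for v in vols:
        present = set(truth.period_presence[v])
        absent_rows = [p not in present for p in lat["period"]]
        abundance.loc[absent_rows, v] = np.nan
    # sample-level nondetects: censored below a per-compound detection limit
    for j, v in enumerate(vols):
        sd = np.sqrt(truth.pathway_loading[v] ** 2 + truth.noise_sd[v] ** 2)
        limit = np.exp(truth.base_log[v] - 2.5 * sd)
        abundance.loc[abundance[v] < limit, v] = np.nan

    for c in SUGARS:
        x = np.exp(lat["sugar_log"][c]
                   + [truth.period_offsets[p][c] for p in lat["period"]])
        abundance[c] = x
    for c in ACIDS:
        x = np.exp(lat["acid_log"][c]
                   + [truth.period_offsets[p][c] for p in lat["period"]])
        abundance[c] = x
    abundance = abundance[list(SUGARS) + list(ACIDS) + vols]

    meta = pd.DataFrame(
        {
            "session": lat["session"],
            "genotype": lat["genotype"],
            "temperature": lat["temperature"],
        },
        index=lat["sample_ids"],
    )
    return ChemicalMatrix(
        abundance=abundance,
        period=pd.Series(lat["period"], index=lat["sample_ids"], name="period"),
        compound_class=pd.Series(truth.compound_class).reindex(abundance.columns),
        sample_meta=meta,
    )


def sample_truth_table(config: SimConfig, truth: SimulationTruth) -> pd.DataFrame:
    """Per-sample systematic sensory means and their building blocks.

    Columns: the standardized drivers (``z_sugar``, ``z_<enhancer>``),
    per-attribute true means (``true_<attr>``), per-attribute sample-level
    residuals (``resid_<attr>``), temperature and metadata.  The true mean
    minus its residual, intercept and temperature term is an exact linear
    function of the drivers, which is what planted-effect recovery tests
    exploit.
    """
    lat = _latent_chemistry(config, truth)
    rng = _rng(config, _STREAM_SENSORY)
    n = config.n_samples
    sigma = config.sensory_total_sd
    sigma2 = sigma ** 2

    out = pd.DataFrame(index=lat["sample_ids"])
    out["period"] = lat["period"]
    out["session"] = lat["session"]
    out["genotype"] = lat["genotype"]
    out["temperature"] = lat["temperature"]
    out["z_sugar"] = lat["z_sugar"]
    out["z_acid"] = lat["z_acid"]
    for v in truth.enhancer_ids:
        out[f"z_{v}"] = lat["z_volatiles"][v]

    enh = np.column_stack(
        [lat["z_volatiles"][v] for v in truth.enhancer_ids]
    ) if truth.enhancer_ids else np.zeros((n, 0))
    sweet_slopes = np.array(
        [truth.sweetness_slopes[v] for v in truth.enhancer_ids]
    )
    lik_slopes = np.array([truth.liking_slopes[v] for v in truth.enhancer_ids])

    frac_enh = config.n_enhancers * config.enhancer_effect
    resid_sweet_sd = np.sqrt(max(sigma2 * (1 - config.sugar_effect - frac_enh), 0.0))
    resid_sweet = resid_sweet_sd * rng.standard_normal(n)
    temp_term = config.temperature_slope * (out["temperature"] - 20.0)

    ic = truth.attribute_intercepts
    out["resid_sweetness"] = resid_sweet
    out["true_sweetness"] = (
        ic["sweetness"]
        + truth.sugar_slope_sweetness * out["z_sugar"]
        + enh @ sweet_slopes
        + temp_term
        + resid_sweet
    )

    # liking: sugars + enhancers + a component shared with the sweetness
    # residual (hedonics track sweetness beyond its chemical drivers) + own
    lik_sugar_frac = 0.75 * config.sugar_effect
    shared_frac = min(0.35, max(1 - lik_sugar_frac - frac_enh - 0.15, 0.0))
    own_frac = max(1 - lik_sugar_frac - frac_enh - shared_frac, 0.0)
    shared = (
        np.sqrt(sigma2 * shared_frac) / resid_sweet_sd * resid_sweet
        if resid_sweet_sd > 0 else 0.0
    )
    resid_lik = shared + np.sqrt(sigma2 * own_frac) * rng.standard_normal(n)
    out["resid_liking"] = resid_lik
    out["true_liking"] = (
        ic["liking"]
        + truth.sugar_slope_liking * out["z_sugar"]
        + enh @ lik_slopes
        + temp_term
        + resid_lik
    )

    resid_tex = 0.6 * resid_lik + 0.7 * sigma * rng.standard_normal(n)
    out["resid_texture_liking"] = resid_tex
    out["true_texture_liking"] = ic["texture_liking"] + resid_tex

    sour_slope = np.sqrt(config.sourness_effect) * sigma
    resid_sour = np.sqrt(sigma2 * (1 - config.sourness_effect)) * rng.standard_normal(n)
    out["resid_sourness"] = resid_sour
    out["true_sourness"] = ic["sourness"] + sour_slope * out["z_acid"] + resid_sour

    resid_flav = 0.5 * resid_sweet + 0.6 * sigma * rng.standard_normal(n)
    out["resid_flavor_intensity"] = resid_flav
    out["true_flavor_intensity"] = (
        ic["flavor_intensity"]
        + 0.6 * truth.sugar_slope_sweetness * out["z_sugar"]
        + 0.6 * (enh @ sweet_slopes)
        + resid_flav
    )
    return out


def generate_sensory_panel(config: SimConfig, truth: SimulationTruth) -> PanelRatings:
    """Long-format panel ratings: sessions, panelist offsets, noise, clipping.

    Each session's samples are rated by that session's own panelists.  Scores
    are Gaussian around the sample's true mean and clipped to the attribute's
    scale; the clipped fraction is available via
    :func:`clipping_fraction`.
    """
    config.validate()
    table = sample_truth_table(config, truth)
    # separate substream from the one sample_truth_table consumes
    rng = np.random.default_rng([int(config.seed), _STREAM_SENSORY, 1])

    frames = []
    npan = config.n_panelists_per_session
    for sess, grp in table.groupby("session", sort=True):
        offsets = config.panelist_sd * rng.standard_normal(npan)
        pids = [f"{sess}_p{j + 1:03d}" for j in range(npan)]
        true = grp[[f"true_{a}" for a in ALL_ATTRIBUTES]].to_numpy()
        noise = config.rating_noise_sd * rng.standard_normal(
            (npan, len(grp), len(ALL_ATTRIBUTES))
        )
        scores = true[None, :, :] + offsets[:, None, None] + noise
        for a_idx, attr in enumerate(ALL_ATTRIBUTES):
            lo, hi = attribute_bounds(attr)
            scores[:, :, a_idx] = np.clip(scores[:, :, a_idx], lo, hi)
        idx = pd.MultiIndex.from_product(
            [pids, grp.index, ALL_ATTRIBUTES],
            names=["panelist_id", "sample_id", "attribute"],
        )
        df = pd.DataFrame({"score": scores.ravel()}, index=idx).reset_index()
        df.insert(1, "session_id", sess)
        frames.append(df)
    rec = pd.concat(frames, ignore_index=True)
    return PanelRatings(
        rec[["panelist_id", "session_id", "sample_id", "attribute", "score"]]
    )


def clipping_fraction(ratings: PanelRatings) -> float:
    """Fraction of emitted scores lying exactly on a scale bound."""
    rec = ratings.records
    at_bound = np.zeros(len(rec), dtype=bool)
    for attr in rec["attribute"].unique():
        lo, hi = attribute_bounds(attr)
        sel = rec["attribute"] == attr
        at_bound |= sel & ((rec["score"] <= lo) | (rec["score"] >= hi))
    return float(at_bound.mean())


def generate_genotypes(
    config: SimConfig, truth: SimulationTruth
) -> tuple[GenotypeMatrix, pd.Series]:
    """Biallelic markers under Hardy-Weinberg plus a log-normal QTL phenotype.

    The QTL marker's additive effect is scaled so it explains
    ``config.qtl_variance`` of the phenotype's variance on the (Gaussian)
    log scale; the returned phenotype is the exponential, i.e. a log-normal
    ester abundance that a Box-Cox transform linearizes.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENO)
    n = config.n_genotyped
    marker_ids = [f"M{i + 1:03d}" for i in range(config.n_markers)]
    freqs = np.full(config.n_markers, np.nan)
    freqs[0] = config.allele_freq  # M001 is the planted QTL
    freqs[1:] = rng.uniform(0.1, 0.9, config.n_markers - 1)
    dosage = rng.binomial(2, freqs, size=(n, config.n_markers)).astype(float)

    p = config.allele_freq
    q = config.qtl_variance
    a = np.sqrt(q / (2 * p * (1 - p)))  # additive effect, total var 1
    noise = np.sqrt(1.0 - q)
    g = dosage[:, 0]
    latent = a * (g - 2 * p) + noise * rng.standard_normal(n)
    pheno = np.exp(np.log(150.0) + latent)

    sample_ids = [f"Q{i + 1:03d}" for i in range(n)]
    gmat = GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=sample_ids, columns=marker_ids),
        marker_map=pd.DataFrame(
            {
                "linkage_group": ["6A"] * config.n_markers,
                "position": np.arange(config.n_markers, dtype=float),
            },
            index=pd.Index(marker_ids, name="marker_id"),
        ),
    )
    return gmat, pd.Series(pheno, index=sample_ids, name="ester_abundance")
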