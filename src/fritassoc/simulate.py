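"""Synthetic five-population study generator.

Emulates the sampling design the analyses assume: five regional populations
in two environment types (northern fragmented: AL, UP; southern continuous:
GO, OL, SA), ~50 full-sib families per population, 49 bi-allelic SNPs with
population-specific minor-allele frequencies (optionally environment-
divergent), and a 21-trait battery with sex, environment, genotype and
environment-by-genotype effects on top of family and population random
deviates. Two parents per family are drawn at Hardy–Weinberg proportions for
their population's allele frequency and offspring receive one uniformly
chosen allele from each parent, so full-sib broods carry the genetic
covariance the family random effect absorbs. Loci are drawn independently
(no inter-locus linkage is modelled).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import SCHEMES, encode_genotype
from .data import (
    MISSING_CALL,
    DataError,
    GenotypeMatrix,
    validate_samples,
    write_samples,
    write_traits,
)

STUDY_POPULATIONS = {
    "AL": "fragmented",
    "UP": "fragmented",
    "GO": "continuous",
    "OL": "continuous",
    "SA": "continuous",
}
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("A", "T"), ("C", "G")]


class SpecError(DataError):
    """Invalid simulation specification."""


@dataclass
class PopulationSpec:
    name: str
    environment: str
    n_families: int
    offspring_per_family: int
    maf_per_locus: list[float]

    def validate(self, n_loci: int) -> None:
        if self.environment not in ("fragmented", "continuous"):
            raise SpecError(f"unknown environment {self.environment!r}")
        if self.n_families < 1:
            raise SpecError(f"population {self.name}: need >= 1 family")
        if self.offspring_per_family < 1:
            raise SpecError(f"population {self.name}: need >= 1 offspring per family")
        if len(self.maf_per_locus) != n_loci:
            raise SpecError(
                f"population {self.name}: {len(self.maf_per_locus)} MAFs for "
                f"{n_loci} loci"
            )
        for f in self.maf_per_locus:
            if not 0.0 <= f <= 0.5:
                raise SpecError(f"population {self.name}: MAF {f} outside [0, 0.5]")


@dataclass
class SnpEffect:
    locus: str
    mode: str  # inheritance scheme of the generating effect
    beta: float  # in residual-SD units

    def validate(self, loci: list[str]) -> None:
        if self.locus not in loci:
            raise SpecError(f"causal locus {self.locus!r} not simulated")
        if self.mode not in SCHEMES:
            raise SpecError(f"unknown inheritance mode {self.mode!r}")


@dataclass
class TraitModel:
    name: str
    intercept: float = 0.0
    sex_effect: float = 0.0  # added for females
    env_effect: float = 0.0  # added in the fragmented environment
    snp_effects: list[SnpEffect] = field(default_factory=list)
    interaction_effects: list[SnpEffect] = field(default_factory=list)
    family_sd: float = 0.0
    population_sd: float = 0.0
    residual_sd: float = 1.0
    proportion: bool = False  # emit through a logistic squash into [0, 1]
    sex_specific: str | None = None  # None | "male" | "female"
    latent: dict[str, float] = field(default_factory=dict)

    def validate(self, loci: list[str]) -> None:
        for sd in (self.family_sd, self.population_sd, self.residual_sd):
            if sd < 0:
                raise SpecError(f"trait {self.name}: negative SD")
        for eff in list(self.snp_effects) + list(self.interaction_effects):
            eff.validate(loci)


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    meta: pd.DataFrame
    traits: pd.DataFrame
    truth: dict
    parents: dict = field(default_factory=dict)  # (pop, family) -> (2, 2, L) alleles


def _locus_names(n_loci: int) -> list[str]:
    return [f"snp{i + 1:02d}" for i in range(n_loci)]


def simulate_genotypes(
    pop_specs: list[PopulationSpec],
    n_loci: int,
    seed: int,
    missing_rate: float = 0.0,
    year: int = 2010,
):
    """Mendelian full-sib genotype simulation.

    Returns (GenotypeMatrix, sample metadata, parents) where parents maps
    (population, family id) to a (2 parents, 2 alleles, n_loci) 0/1 array
    (1 = minor allele).
    """
    if n_loci < 1:
        raise SpecError("n_loci must be >= 1")
    for spec in pop_specs:
        spec.validate(n_loci)
    rng = np.random.default_rng(seed)
    loci = _locus_names(n_loci)
    letters = [
        _ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=n_loci)
    ]  # (major, minor) per locus
    rows, meta_rows, index = [], [], []
    parents: dict = {}
    for spec in pop_specs:
        maf = np.asarray(spec.maf_per_locus)
        for fam in range(spec.n_families):
            fam_id = f"{spec.name}_F{fam + 1:03d}"
            par = (rng.random((2, 2, n_loci)) < maf).astype(np.int8)
            parents[(spec.name, fam_id)] = par
            for off in range(spec.offspring_per_family):
                pick = rng.integers(0, 2, size=(2, n_loci))
                alleles = par[np.arange(2)[:, None], pick, np.arange(n_loci)]
                calls = []
                for j in range(n_loci):
                    pair = sorted(letters[j][a] for a in alleles[:, j])
                    calls.append("".join(pair))
                sid = f"{spec.name}_F{fam + 1:03d}_{off + 1}"
                index.append(sid)
                rows.append(calls)
                meta_rows.append({
                    "population": spec.name,
                    "environment": spec.environment,
                    "sex": "female" if rng.random() < 0.5 else "male",
                    "family": fam_id,
                    "year": str(year),
                })
    df = pd.DataFrame(rows, index=index, columns=loci)
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns),
                     MISSING_CALL)
    meta = validate_samples(pd.DataFrame(meta_rows, index=index).rename_axis("sample_id"))
    return GenotypeMatrix(df), meta, parents


def simulate_traits(
    geno: GenotypeMatrix,
    meta: pd.DataFrame,
    models: list[TraitModel],
    seed: int,
) -> pd.DataFrame:
    """Generate the trait table from the linear generative model.

    trait = intercept + sex + environment + sum(encoded genotype x effect)
    + environment-by-genotype terms + latent factors + family deviate +
    population deviate + residual; proportion traits pass through a logistic
    squash into [0, 1]. Missing genotype calls contribute their locus-mean
    encoded value.
    """
    rng = np.random.default_rng(seed)
    for m in models:
        m.validate(geno.loci)
    minor = geno.minor_counts()
    n = len(meta)
    female = (meta["sex"] == "female").to_numpy(dtype=float)
    frag = (meta["environment"] == "fragmented").to_numpy(dtype=float)
    factors = sorted({f for m in models for f in m.latent})
    latent = {f: rng.standard_normal(n) for f in factors}
    fams = sorted(meta["family"].unique())
    pops = sorted(meta["population"].unique())
    fam_idx = meta["family"].map({f: i for i, f in enumerate(fams)}).to_numpy()
    pop_idx = meta["population"].map({p: i for i, p in enumerate(pops)}).to_numpy()

    def encoded(eff: SnpEffect) -> np.ndarray:
        code = encode_genotype(minor[eff.locus].to_numpy(), eff.mode)
        m = np.nanmean(code)
        return np.where(np.isfinite(code), code, 0.0 if np.isnan(m) else m)

    out = {}
    for m in models:
        y = np.full(n, m.intercept, dtype=float)
        y += m.sex_effect * female + m.env_effect * frag
        for eff in m.snp_effects:
            y += eff.beta * m.residual_sd * encoded(eff)
        for eff in m.interaction_effects:
            y += eff.beta * m.residual_sd * encoded(eff) * frag
        for f, loading in m.latent.items():
            y += loading * latent[f]
        y += rng.standard_normal(len(fams))[fam_idx] * m.family_sd
        y += rng.standard_normal(len(pops))[pop_idx] * m.population_sd
        y += rng.standard_normal(n) * m.residual_sd
        if m.proportion:
            y = 1.0 / (1.0 + np.exp(-y))
        if m.sex_specific == "male":
            y = np.where(female == 1.0, np.nan, y)
        elif m.sex_specific == "female":
            y = np.where(female == 0.0, np.nan, y)
        out[m.name] = y
    return pd.DataFrame(out, index=meta.index).rename_axis("sample_id")


# ---------------------------------------------------------------------------
# study-scale defaults


def default_population_specs(
    seed: int,
    n_loci: int = 49,
    n_families: int = 50,
    offspring_per_family: int = 1,
    divergent: dict[str, tuple[float, float]] | None = None,
    maf_override: dict[str, float] | None = None,
    jitter: float = 0.03,
) -> list[PopulationSpec]:
    """Five study populations with shared base MAFs plus small per-population
    jitter; ``divergent`` maps locus name -> (fragmented MAF, continuous MAF)
    and ``maf_override`` pins a locus to one MAF in every population (e.g. a
    focal locus at the study's typical 0.3).
    """
    rng = np.random.default_rng(seed)
    loci = _locus_names(n_loci)
    base = rng.uniform(0.1, 0.5, size=n_loci)
    divergent = divergent or {}
    maf_override = maf_override or {}
    specs = []
    for name, env in STUDY_POPULATIONS.items():
        maf = np.clip(base + rng.uniform(-jitter, jitter, size=n_loci), 0.05, 0.5)
        for locus, f in maf_override.items():
            maf[loci.index(locus)] = f
        for locus, (f_frag, f_cont) in divergent.items():
            maf[loci.index(locus)] = f_frag if env == "fragmented" else f_cont
        specs.append(PopulationSpec(name, env, n_families, offspring_per_family,
                                    [float(v) for v in maf]))
    return specs


def default_trait_models(
    causal: list[SnpEffect] | None = None,
    interaction: list[SnpEffect] | None = None,
    family_sd: float = 0.5,
    population_sd: float = 0.3,
) -> list[TraitModel]:
    """The 21-trait battery: 9 development, 6 male-adult, 6 female-adult.

    ``causal`` effects are applied to every development trait (shared genetic
    influence on growth), which lets them surface in the leading development
    component.
    """
    causal = causal or []
    interaction = interaction or []

    def tm(name, **kw):
        return TraitModel(name=name, family_sd=family_sd,
                          population_sd=population_sd, **kw)

    development = [
        tm("larva_weight_5th", sex_effect=0.6, env_effect=0.2, latent={"size": 0.9}),
        tm("larva_weight_6th", sex_effect=0.6, env_effect=0.2, latent={"size": 1.0}),
        tm("larva_weight_7th", sex_effect=0.7, env_effect=0.2, latent={"size": 1.1}),
        tm("pupal_weight", sex_effect=0.8, env_effect=0.2, latent={"size": 1.2}),
        tm("molt_interval_5_6", env_effect=-0.1, latent={"tempo": 0.9}),
        tm("molt_interval_6_7", env_effect=-0.1, latent={"tempo": 1.0}),
        tm("larval_period", sex_effect=-0.3, env_effect=-0.2, latent={"tempo": 1.2}),
        tm("pupal_period", latent={"tempo": 0.8}),
        tm("growth_rate", sex_effect=0.3, latent={"size": 0.6, "tempo": -0.5}),
    ]
    for t in development:
        t.snp_effects = list(causal)
        t.interaction_effects = list(interaction)
    male = [
        tm("age_first_mating", sex_specific="male", latent={"vigor": -0.8}),
        tm("mating_success", sex_specific="male", latent={"vigor": 1.0}),
        tm("flight_probability", sex_specific="male", proportion=True,
           latent={"vigor": 0.9}),
        tm("move_distance", sex_specific="male", latent={"vigor": 1.1}),
        tm("male_survival", sex_specific="male", latent={"vigor": 0.5}),
        tm("male_activity", sex_specific="male", latent={"vigor": 0.7}),
    ]
    female = [
        tm("age_first_oviposition", sex_specific="female", latent={"fecundity": -0.6}),
        tm("total_clutches", sex_specific="female", latent={"fecundity": 1.0}),
        tm("total_eggs", sex_specific="female", latent={"fecundity": 1.2}),
        tm("hatch_rate", sex_specific="female", proportion=True,
           latent={"fecundity": 0.8}),
        tm("host_preference", sex_specific="female", proportion=True),
        tm("female_survival", sex_specific="female", latent={"fecundity": 0.4}),
    ]
    return development + male + female


def default_battery_config() -> dict:
    """Battery membership matching :func:`default_trait_models`."""
    return {
        "development": {
            "traits": ["larva_weight_5th", "larva_weight_6th", "larva_weight_7th",
                       "pupal_weight", "molt_interval_5_6", "molt_interval_6_7",
                       "larval_period", "pupal_period", "growth_rate"],
            "proportions": [],
        },
        "male_adult": {
            "traits": ["age_first_mating", "mating_success", "flight_probability",
                       "move_distance", "male_survival", "male_activity"],
            "proportions": ["flight_probability"],
        },
        "female_adult": {
            "traits": ["age_first_oviposition", "total_clutches", "total_eggs",
                       "hatch_rate", "host_preference", "female_survival"],
            "proportions": ["hatch_rate", "host_preference"],
        },
    }


def _models_to_dicts(models: list[TraitModel]) -> list[dict]:
    return [asdict(m) for m in models]


def _models_from_dicts(dicts: list[dict]) -> list[TraitModel]:
    models = []
    for d in dicts:
        d = dict(d)
        d["snp_effects"] = [SnpEffect(**e) for e in d.get("snp_effects", [])]
        d["interaction_effects"] = [SnpEffect(**e)
                                    for e in d.get("interaction_effects", [])]
        models.append(TraitModel(**d))
    return models


def generate_from_truth(truth: dict) -> SyntheticDataset:
    """Deterministically rebuild a dataset from its ground-truth record."""
    specs = [PopulationSpec(**d) for d in truth["populations"]]
    models = _models_from_dicts(truth["trait_models"])
    geno, meta, parents = simulate_genotypes(
        specs, truth["n_loci"], truth["genotype_seed"],
        missing_rate=truth.get("missing_rate", 0.0),
    )
    traits = simulate_traits(geno, meta, models, truth["trait_seed"])
    return SyntheticDataset(geno, meta, traits, truth, parents)


def study_dataset(
    seed: int,
    causal: list[SnpEffect] | None = None,
    interaction: list[SnpEffect] | None = None,
    divergent: dict[str, tuple[float, float]] | None = None,
    maf_override: dict[str, float] | None = None,
    n_loci: int = 49,
    n_families: int = 50,
    offspring_per_family: int = 1,
    missing_rate: float = 0.02,
) -> SyntheticDataset:
    """The packaged study-scale fixture: 5 populations x 50 families x 1
    offspring, 49 loci, 21 traits."""
    ss = np.random.SeedSequence(seed)
    s_spec, s_geno, s_trait = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    specs = default_population_specs(
        s_spec, n_loci=n_loci, n_families=n_families,
        offspring_per_family=offspring_per_family, divergent=divergent,
        maf_override=maf_override,
    )
    models = default_trait_models(causal=causal, interaction=interaction)
    truth = {
        "seed": seed,
        "genotype_seed": s_geno,
        "trait_seed": s_trait,
        "missing_rate": missing_rate,
        "n_loci": n_loci,
        "populations": [asdict(s) for s in specs],
        "trait_models": _models_to_dicts(models),
        "causal": [asdict(e) for e in (causal or [])],
        "divergent": {k: list(v) for k, v in (divergent or {}).items()},
    }
    return generate_from_truth(truth)


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict:
    """Write genotypes/samples/traits TSVs plus the truth sidecar.

    Returns a manifest of paths; regeneration from the recorded seeds
    reproduces the files exactly.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": directory / "genotypes.tsv",
            "samples": directory / "samples.tsv",
            "traits": directory / "traits.tsv",
            "truth": directory / "truth.yaml",
        }
        dataset.genotypes.to_tsv(paths["genotypes"])
        write_samples(dataset.meta, paths["samples"])
        write_traits(dataset.traits, paths["traits"])
        with open(paths["truth"], "w") as fh:
            yaml.safe_dump(dataset.truth, fh, sort_keys=True)
    except OSError as exc:
        raise DataError(f"cannot write fixture under {directory}: {exc}") from exc
    return {k: str(v) for k, v in paths.items()}


def read_fixture(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    from .data import read_samples, read_traits

    geno = GenotypeMatrix.from_tsv(directory / "genotypes.tsv")
    meta = read_samples(directory / "samples.tsv")
    traits = read_traits(directory / "traits.tsv")
    with open(directory / "truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    return SyntheticDataset(geno, meta, traits, truth)
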