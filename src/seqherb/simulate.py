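"""Synthetic sequential-herbivory datasets with known generating truth.

The generator emulates the statistical structure the analysis assumes: many
studies, each contributing one or more induction treatments that share a
control, each treatment contributing one or more measured outcomes; true
effects carry between-study and between-treatment-within-study heterogeneity
on top of known sampling error; moderators (guilds, diet breadths, feeding
locations, plant traits, experimental design) are attached per record; and a
subset of survival/choice records reports binary event counts instead of
means, analysed on the log odds ratio scale.

Raw per-arm summaries (means, SDs, n) are generated — not effect values
directly — so that the effect-size computation is exercised end to end: arm
SDs are drawn from the chi distribution implied by normal sampling, and arm
means from their normal sampling distributions around the configured true
standardized difference.

Every random draw is namespaced by (stream, study, treatment, record) through
``numpy.random.SeedSequence`` spawn keys, so datasets are bit-reproducible
from (config, seed) and adding studies does not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .dataset_io import CANONICAL_COLUMNS, CATEGORY_OUTCOMES, Dataset
from .effect_sizes import SIGN_REVERSED_OUTCOMES


class ConfigError(ValueError):
    """Raised before sampling when a configuration is infeasible."""


# (species, life_cycle, growth_form, status, weight%) — representation weights
# shaped to the species spectrum typical of sequential-herbivory experiments,
# with the three most-studied plants carrying 13.5 / 11.8 / 10.8% of records.
PLANT_SPECIES = (
    ("Brassica oleracea", "annual", "herbaceous", "cultivated", 13.5),
    ("Brassica nigra", "annual", "herbaceous", "wild", 11.8),
    ("Solanum lycopersicum", "annual", "herbaceous", "cultivated", 10.8),
    ("Nicotiana attenuata", "annual", "herbaceous", "wild", 6.0),
    ("Zea mays", "annual", "herbaceous", "cultivated", 6.0),
    ("Arabidopsis thaliana", "annual", "herbaceous", "wild", 5.0),
    ("Gossypium hirsutum", "annual", "herbaceous", "cultivated", 5.0),
    ("Phaseolus lunatus", "annual", "herbaceous", "cultivated", 4.0),
    ("Sinapis alba", "annual", "herbaceous", "wild", 4.0),
    ("Solanum dulcamara", "perennial", "herbaceous", "wild", 4.0),
    ("Oryza sativa", "annual", "herbaceous", "cultivated", 3.9),
    ("Taraxacum officinale", "perennial", "herbaceous", "wild", 3.5),
    ("Plantago lanceolata", "perennial", "herbaceous", "wild", 3.5),
    ("Medicago sativa", "perennial", "herbaceous", "cultivated", 3.5),
    ("Betula pendula", "perennial", "woody", "wild", 3.5),
    ("Salix exigua", "perennial", "woody", "wild", 3.0),
    ("Quercus robur", "perennial", "woody", "wild", 3.0),
    ("Pinus sylvestris", "perennial", "woody", "wild", 2.5),
    ("Malus domestica", "perennial", "woody", "cultivated", 2.5),
    ("Vitis vinifera", "perennial", "woody", "cultivated", 2.0),
)

# (species, guild, diet, location, weight%) for the inducing herbivore; the
# three most-studied inducers carry 5.9 / 5.5 / 5.4%, mammals ~1% of records.
INDUCER_SPECIES = (
    ("Brevicoryne brassicae", "sap_feeder", "specialist", "aboveground", 5.9),
    ("Plutella xylostella", "chewer", "specialist", "aboveground", 5.5),
    ("Meloidogyne incognita", "nematode", "generalist", "belowground", 5.4),
    ("Pieris brassicae", "chewer", "specialist", "aboveground", 5.0),
    ("Spodoptera exigua", "chewer", "generalist", "aboveground", 5.0),
    ("Myzus persicae", "sap_feeder", "generalist", "aboveground", 4.5),
    ("Manduca sexta", "chewer", "specialist", "aboveground", 4.5),
    ("Helicoverpa zea", "chewer", "generalist", "aboveground", 4.5),
    ("Trichoplusia ni", "chewer", "generalist", "aboveground", 4.0),
    ("Tetranychus urticae", "mite", "generalist", "aboveground", 4.0),
    ("Aphis gossypii", "sap_feeder", "generalist", "aboveground", 4.0),
    ("Bemisia tabaci", "sap_feeder", "generalist", "aboveground", 4.0),
    ("Spodoptera littoralis", "chewer", "generalist", "aboveground", 4.0),
    ("Mamestra brassicae", "chewer", "generalist", "aboveground", 4.0),
    ("Athalia rosae", "chewer", "specialist", "aboveground", 3.7),
    ("Frankliniella occidentalis", "sap_feeder", "generalist", "aboveground", 3.5),
    ("Nilaparvata lugens", "sap_feeder", "specialist", "aboveground", 3.5),
    ("Leptinotarsa decemlineata", "chewer", "specialist", "aboveground", 3.5),
    ("Diabrotica virgifera", "chewer", "specialist", "belowground", 3.5),
    ("Agriotes lineatus", "chewer", "generalist", "belowground", 3.0),
    ("Heterodera schachtii", "nematode", "specialist", "belowground", 3.0),
    ("Pratylenchus penetrans", "nematode", "generalist", "belowground", 3.0),
    ("Delia radicum", "chewer", "specialist", "belowground", 3.0),
    ("Spodoptera frugiperda", "chewer", "generalist", "aboveground", 3.0),
    ("Acyrthosiphon pisum", "sap_feeder", "specialist", "aboveground", 3.0),
    ("Odocoileus virginianus", "mammal_browser", "generalist", "aboveground", 0.5),
    ("Capreolus capreolus", "mammal_browser", "generalist", "aboveground", 0.5),
)

# Subsequent herbivores (no mammals): top three carry 7.4 / 5.9 / 5.9%.
SUBSEQUENT_SPECIES = (
    ("Tetranychus urticae", "mite", "generalist", "aboveground", 7.4),
    ("Myzus persicae", "sap_feeder", "generalist", "aboveground", 5.9),
    ("Plutella xylostella", "chewer", "specialist", "aboveground", 5.9),
    ("Spodoptera exigua", "chewer", "generalist", "aboveground", 5.5),
    ("Pieris brassicae", "chewer", "specialist", "aboveground", 5.5),
    ("Brevicoryne brassicae", "sap_feeder", "specialist", "aboveground", 5.0),
    ("Trichoplusia ni", "chewer", "generalist", "aboveground", 5.0),
    ("Manduca sexta", "chewer", "specialist", "aboveground", 5.0),
    ("Helicoverpa zea", "chewer", "generalist", "aboveground", 4.8),
    ("Mamestra brassicae", "chewer", "generalist", "aboveground", 4.5),
    ("Spodoptera littoralis", "chewer", "generalist", "aboveground", 4.5),
    ("Bemisia tabaci", "sap_feeder", "generalist", "aboveground", 4.5),
    ("Aphis gossypii", "sap_feeder", "generalist", "aboveground", 4.5),
    ("Frankliniella occidentalis", "sap_feeder", "generalist", "aboveground", 4.0),
    ("Athalia rosae", "chewer", "specialist", "aboveground", 4.0),
    ("Leptinotarsa decemlineata", "chewer", "specialist", "aboveground", 4.0),
    ("Spodoptera frugiperda", "chewer", "generalist", "aboveground", 4.0),
    ("Acyrthosiphon pisum", "sap_feeder", "specialist", "aboveground", 3.5),
    ("Meloidogyne incognita", "nematode", "generalist", "belowground", 3.5),
    ("Heterodera schachtii", "nematode", "specialist", "belowground", 3.0),
    ("Pratylenchus penetrans", "nematode", "generalist", "belowground", 3.0),
    ("Delia radicum", "chewer", "specialist", "belowground", 3.0),
)

OUTCOME_WEIGHTS = {
    "herbivore_performance": (("growth", 0.40), ("survival", 0.25), ("fecundity", 0.20), ("development_time", 0.15)),
    "herbivore_preference": (("feeding_choice", 0.55), ("oviposition_choice", 0.45)),
    "plant_performance": (("biomass", 0.50), ("damage", 0.40), ("reproduction", 0.10)),
}

_STREAM_STUDY, _STREAM_TRT, _STREAM_REC, _STREAM_U = 1, 2, 3, 4


@dataclass
class SimulationConfig:
    """Generating parameters of one synthetic dataset.

    Per-category maps may also be given as scalars applying to all
    categories.  Variances are on the effect-size (g or LOR) scale; means of
    the three response categories default to the magnitudes typical of
    sequential-herbivory meta-analytic data (clear induced resistance in
    herbivore performance, weak effects in preference and plant
    performance), and the heterogeneity defaults reproduce the very high
    multilevel I² (85–95%) characteristic of ecological effect-size sets.
    """

    n_studies: int = 161
    treatments_per_study: tuple[int, int] = (1, 4)
    records_per_treatment: tuple[int, int] = (1, 6)
    group_size_range: tuple[int, int] = (5, 30)
    category_means: dict[str, float] = field(
        default_factory=lambda: {
            "herbivore_performance": -0.326,
            "herbivore_preference": -0.142,
            "plant_performance": -0.013,
        }
    )
    category_weights: dict[str, float] = field(
        default_factory=lambda: {
            "herbivore_performance": 834.0,
            "herbivore_preference": 339.0,
            "plant_performance": 172.0,
        }
    )
    sigma2_study: dict[str, float] | float = field(
        default_factory=lambda: {
            "herbivore_performance": 0.62,
            "herbivore_preference": 1.66,
            "plant_performance": 0.50,
        }
    )
    sigma2_treatment: dict[str, float] | float = field(
        default_factory=lambda: {
            "herbivore_performance": 0.38,
            "herbivore_preference": 1.01,
            "plant_performance": 0.31,
        }
    )
    sigma2_taxon: float = 0.0
    taxon_corr: Any = None  # PhyloCorrelation over plant species, optional
    sd_scale: float = 1.0
    binary_fraction: float = 0.10
    binary_group_size_range: tuple[int, int] = (15, 60)
    lor_means: dict[str, float] = field(
        default_factory=lambda: {
            "survival": -0.80,
            "feeding_choice": -0.05,
            "oviposition_choice": -0.75,
        }
    )
    sigma2_study_binary: float = 0.15
    sigma2_treatment_binary: float = 0.09
    control_rate_range: tuple[float, float] = (0.50, 0.85)
    choice_rate_range: tuple[float, float] = (0.35, 0.65)
    year_range: tuple[int, int] = (1985, 2023)
    same_species_prob: float = 0.08
    field_prob: float = 0.15
    inducer_removed_prob: float = 0.80
    moderator_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("setting", "field"): 0.25,
            ("guild_pair", "sap_feeder->chewer"): 0.15,
        }
    )
    small_study_bias: float = 0.0
    seed: int = 0

    @staticmethod
    def recovery(seed: int = 0) -> "SimulationConfig":
        """Single-category config used for parameter-recovery studies:
        150 studies, 1–4 treatments, true mean -0.33, σ²_study 0.2, σ²_trt 0.1."""
        return SimulationConfig(
            n_studies=150,
            treatments_per_study=(1, 4),
            records_per_treatment=(1, 2),
            category_means={"herbivore_performance": -0.33},
            category_weights={"herbivore_performance": 1.0},
            sigma2_study=0.2,
            sigma2_treatment=0.1,
            binary_fraction=0.0,
            moderator_effects={},
            seed=seed,
        )

    def validate(self) -> None:
        for name in ("treatments_per_study", "records_per_treatment", "group_size_range", "binary_group_size_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} range ({lo}, {hi}) is empty or invalid")
        if self.n_studies < 1:
            raise ConfigError("n_studies must be positive")
        for cat in self.category_means:
            if self._s2(self.sigma2_study, cat) < 0 or self._s2(self.sigma2_treatment, cat) < 0:
                raise ConfigError("variance components must be nonnegative")
        if not 0 <= self.binary_fraction <= 1:
            raise ConfigError("binary_fraction must lie in [0, 1]")
        if self.sd_scale <= 0:
            raise ConfigError("sd_scale must be positive")
        for lo, hi in (self.control_rate_range, self.choice_rate_range):
            if not (0 < lo <= hi < 1):
                raise ConfigError("binary rate ranges must lie inside (0, 1)")
        if self.year_range[1] < self.year_range[0]:
            raise ConfigError("year_range is empty")
        if set(self.category_weights) != set(self.category_means):
            raise ConfigError("category_weights and category_means must share keys")
        if self.sigma2_taxon < 0:
            raise ConfigError("sigma2_taxon must be nonnegative")
        if self.sigma2_taxon > 0 and self.taxon_corr is None:
            raise ConfigError("sigma2_taxon > 0 requires taxon_corr")

    @staticmethod
    def _s2(value: dict[str, float] | float, cat: str) -> float:
        return float(value[cat]) if isinstance(value, dict) else float(value)


@dataclass
class SimulationTruth:
    """The realized random deviates and the config that generated them."""

    config: SimulationConfig
    u_study: dict[tuple[str, str], float]
    u_treatment: dict[tuple[str, str], float]
    u_taxon: dict[str, float]
    theta: dict[str, float]  # record_id -> true effect (g or LOR scale)
    metric: dict[str, str]

    def to_json(self) -> dict[str, Any]:
        cfg = asdict(self.config)
        cfg.pop("taxon_corr", None)
        cfg["moderator_effects"] = {
            f"{col}={lev}": eff for (col, lev), eff in self.config.moderator_effects.items()
        }
        return {
            "config": _jsonable(cfg),
            "u_study": {f"{s}|{c}": u for (s, c), u in self.u_study.items()},
            "u_treatment": {f"{t}|{c}": u for (t, c), u in self.u_treatment.items()},
            "u_taxon": dict(self.u_taxon),
            "theta": dict(self.theta),
            "metric": dict(self.metric),
        }


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _pick(rng: np.random.Generator, table: tuple) -> tuple:
    weights = np.array([row[-1] for row in table], dtype=float)
    return table[rng.choice(len(table), p=weights / weights.sum())]


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, SimulationTruth]:
    """Generate one dataset plus its generating truth, reproducibly from
    (config, config.seed)."""
    config.validate()
    seed = config.seed
    cats = sorted(config.category_means)
    cat_w = np.array([config.category_weights[c] for c in cats], dtype=float)
    cat_w /= cat_w.sum()

    u_taxon: dict[str, float] = {}
    if config.sigma2_taxon > 0:
        corr = config.taxon_corr
        rng_tax = _rng(seed, _STREAM_U, 0)
        L = np.linalg.cholesky(
            np.asarray(corr.matrix) + 1e-10 * np.eye(len(corr.taxa))
        )
        draws = math.sqrt(config.sigma2_taxon) * (L @ rng_tax.standard_normal(len(corr.taxa)))
        u_taxon = {t: float(d) for t, d in zip(corr.taxa, draws)}

    rows: list[dict[str, Any]] = []
    u_study: dict[tuple[str, str], float] = {}
    u_trt: dict[tuple[str, str], float] = {}
    theta_truth: dict[str, float] = {}
    metric_truth: dict[str, str] = {}

    for s in range(config.n_studies):
        study_id = f"S{s + 1:03d}"
        rs = _rng(seed, _STREAM_STUDY, s)
        plant = _pick(rs, PLANT_SPECIES)
        subsequent = _pick(rs, SUBSEQUENT_SPECIES)
        year = int(
            config.year_range[0]
            + math.floor((config.year_range[1] - config.year_range[0] + 1) * rs.beta(2.5, 1.0))
        )
        year = min(year, config.year_range[1])
        setting = "field" if rs.random() < config.field_prob else "glasshouse"
        n_trt = int(rs.integers(config.treatments_per_study[0], config.treatments_per_study[1] + 1))

        for cat in cats:
            ru = _rng(seed, _STREAM_U, s, cats.index(cat), 0)
            u_study[(study_id, cat)] = float(
                math.sqrt(config._s2(config.sigma2_study, cat)) * ru.standard_normal()
            )
            u_study[(study_id, cat + "|binary")] = float(
                math.sqrt(config.sigma2_study_binary) * ru.standard_normal()
            )

        for t in range(n_trt):
            treatment_id = f"{study_id}_T{t + 1}"
            rt = _rng(seed, _STREAM_TRT, s, t)
            if rt.random() < config.same_species_prob:
                inducer = next(
                    (row for row in INDUCER_SPECIES if row[0] == subsequent[0]),
                    (subsequent[0], subsequent[1], subsequent[2], subsequent[3], 1.0),
                )
            else:
                inducer = _pick(rt, INDUCER_SPECIES)
            inducer_removed = bool(rt.random() < config.inducer_removed_prob)
            duration_first = float(np.round(np.exp(rt.normal(math.log(7.0), 0.8)), 1))
            duration_second = float(np.round(np.exp(rt.normal(math.log(7.0), 0.8)), 1))
            n_rec = int(rt.integers(config.records_per_treatment[0], config.records_per_treatment[1] + 1))

            for cat in cats:
                ru = _rng(seed, _STREAM_U, s, cats.index(cat), 1 + t)
                u_trt[(treatment_id, cat)] = float(
                    math.sqrt(config._s2(config.sigma2_treatment, cat)) * ru.standard_normal()
                )
                u_trt[(treatment_id, cat + "|binary")] = float(
                    math.sqrt(config.sigma2_treatment_binary) * ru.standard_normal()
                )

            for r in range(n_rec):
                record_id = f"{treatment_id}_R{r + 1}"
                rr = _rng(seed, _STREAM_REC, s, t, r)
                cat = cats[rr.choice(len(cats), p=cat_w)]
                outs, ow = zip(*OUTCOME_WEIGHTS[cat])
                outcome = outs[rr.choice(len(outs), p=np.array(ow) / sum(ow))]

                row: dict[str, Any] = {
                    "record_id": record_id,
                    "study_id": study_id,
                    "treatment_id": treatment_id,
                    "response_category": cat,
                    "outcome": outcome,
                    "publication_year": year,
                    "setting": setting,
                    "inducer_removed": inducer_removed,
                    "duration_first": duration_first,
                    "duration_second": duration_second,
                    "plant_species": plant[0],
                    "plant_life_cycle": plant[1],
                    "plant_growth_form": plant[2],
                    "plant_status": plant[3],
                    "inducer_species": inducer[0],
                    "inducer_guild": inducer[1],
                    "inducer_diet": inducer[2],
                    "inducer_location": inducer[3],
                    "subsequent_species": subsequent[0],
                    "subsequent_guild": subsequent[1],
                    "subsequent_diet": subsequent[2],
                    "subsequent_location": subsequent[3],
                    "same_species": inducer[0] == subsequent[0],
                }

                binary = (
                    outcome in config.lor_means
                    and rr.random() < config.binary_fraction
                )
                if binary:
                    theta = (
                        config.lor_means[outcome]
                        + u_study[(study_id, cat + "|binary")]
                        + u_trt[(treatment_id, cat + "|binary")]
                    )
                    lo, hi = (
                        config.control_rate_range
                        if outcome == "survival"
                        else config.choice_rate_range
                    )
                    p_c = float(rr.uniform(lo, hi))
                    p_t = 1.0 / (1.0 + math.exp(-(math.log(p_c / (1 - p_c)) + theta)))
                    n_t = int(rr.integers(*_incl(config.binary_group_size_range)))
                    n_c = int(rr.integers(*_incl(config.binary_group_size_range)))
                    row.update(
                        n_treatment=n_t,
                        n_control=n_c,
                        events_treatment=int(rr.binomial(n_t, p_t)),
                        events_control=int(rr.binomial(n_c, p_c)),
                        mean_treatment=np.nan,
                        mean_control=np.nan,
                        sd_treatment=np.nan,
                        sd_control=np.nan,
                    )
                    metric_truth[record_id] = "log_odds_ratio"
                else:
                    theta = (
                        config.category_means[cat]
                        + u_study[(study_id, cat)]
                        + u_trt[(treatment_id, cat)]
                        + u_taxon.get(plant[0], 0.0)
                    )
                    for (col, lev), eff in config.moderator_effects.items():
                        val = (
                            f"{inducer[1]}->{subsequent[1]}"
                            if col == "guild_pair"
                            else row.get(col)
                        )
                        if val == lev:
                            theta += eff
                    n_t = int(rr.integers(*_incl(config.group_size_range)))
                    n_c = int(rr.integers(*_incl(config.group_size_range)))
                    if config.small_study_bias:
                        theta += config.small_study_bias * math.sqrt(
                            (n_t + n_c) / (n_t * n_c)
                        )
                    s0 = config.sd_scale
                    raw_mean = -theta if outcome in SIGN_REVERSED_OUTCOMES else theta
                    sd_t = s0 * math.sqrt(rr.chisquare(n_t - 1) / (n_t - 1)) if n_t > 1 else s0
                    sd_c = s0 * math.sqrt(rr.chisquare(n_c - 1) / (n_c - 1)) if n_c > 1 else s0
                    row.update(
                        n_treatment=n_t,
                        n_control=n_c,
                        mean_treatment=float(rr.normal(raw_mean * s0, s0 / math.sqrt(n_t))),
                        mean_control=float(rr.normal(0.0, s0 / math.sqrt(n_c))),
                        sd_treatment=sd_t,
                        sd_control=sd_c,
                        events_treatment=np.nan,
                        events_control=np.nan,
                    )
                    metric_truth[record_id] = "hedges_g"
                theta_truth[record_id] = float(theta)
                rows.append(row)

    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    dataset = Dataset(frame, {"source": "simulate_dataset", "seed": seed})
    truth = SimulationTruth(
        config=config,
        u_study=u_study,
        u_treatment=u_trt,
        u_taxon=u_taxon,
        theta=theta_truth,
        metric=metric_truth,
    )
    return dataset, truth


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def simulate_tree(taxa: list[str], seed: int = 0):
    """Reproducible random ultrametric (pure-birth-style) tree over the taxa.

    Built by joining random pairs of lineages backward in time with
    exponential waiting times (rate proportional to the number of open
    lineages), then reading node ages as depths; all branch lengths are
    strictly positive and every tip sits at the same depth.
    """
    import dendropy

    if len(taxa) < 2:
        raise ConfigError("a tree needs at least 2 taxa")
    rng = _rng(seed, 7)
    ns = dendropy.TaxonNamespace(sorted(taxa))
    nodes = []
    for taxon in ns:
        nd = dendropy.Node(taxon=taxon)
        nd.age = 0.0
        nodes.append(nd)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += float(rng.exponential(1.0 / k))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.age = t
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = parent.age - a.age
        b.edge.length = parent.age - b.age
        nodes = [nd for nd in nodes if nd not in (a, b)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return tree
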