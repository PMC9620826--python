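"""Synthetic cohort generator with planted Mendelian-disease signal.

Real score analyses run on restricted clinical and genotype data, so the
package ships a generator that emulates every input the pipeline needs:
demographics, ICD occurrences with a covariate-dependent background code
burden, diagnostic codes for planted cases, and Hardy-Weinberg genotypes
whose pathogenic variants shift the raw score of homozygous (and
optionally heterozygous) carriers by a configured amount.

What is emulated, and how:

* Demographics: sex ~ Bernoulli(0.5); age at first visit uniform on
  0-90 years; visit span exponential (mean 5 years, floored at 30 days
  so two distinct diagnostic dates always fit).
* Background ICD occurrences: per-person Poisson counts with rate
  ``background_code_rate`` scaled by log-linear sex/age/span effects;
  codes drawn from the ICD->phecode map (diagnostic codes excluded so
  case status stays clean), with disease-feature codes at a quarter of
  the filler-code frequency so carriers rarely already have a feature,
  plus two deliberately unmappable codes.
* Cases: for each configured disease, ``n_cases`` persons emit each
  feature phecode's source ICD code with probability
  ``feature_emission_prob`` and receive a diagnostic code on two
  distinct dates; n_cases // 5 further persons get a single-date
  diagnostic posting to populate the 'neither' status.
* Genotypes: allele counts Binomial(2, q), i.e. Hardy-Weinberg.
  Carriers of an effect variant receive extra feature-code emissions
  calibrated per person so the expected raw-score shift equals the
  configured effect: the linked disease's lacking phecodes are emitted
  greedily in decreasing-weight order while their summed weight stays
  below the effect, then one further phecode is emitted with the
  Bernoulli probability that tops the expectation up to the effect
  exactly. The greedy-plus-top-up scheme keeps the carrier-level shift
  variance near the minimum a discrete emission process allows, so the
  planted effect is identifiable at modest homozygote counts. Weights
  for the calibration come from the pre-boost cohort, so realized
  shifts feed back on the final weights only marginally (carriers are
  rare). A carrier already holding every feature phecode (summed
  lacking weight below the effect) receives the largest shift still
  available; the per-variant truth record stores the mean expected
  shift actually delivered.

All randomness flows from one ``numpy.random.default_rng(seed)``; there
is no global state, and identical config yields identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import ValidationError
from .maps import BundledMaps, load_bundled_maps
from .phecoding import map_icd_to_phecodes
from .weights import calc_weights

logger = logging.getLogger("phers")

BASE_DATE = pd.Timestamp("2005-01-01")
DAYS_PER_YEAR = 365.25


@dataclass
class DiseaseSignal:
    """A disease with planted cases: each case emits every feature
    phecode's source ICD code with probability feature_emission_prob."""
    disease_id: str
    n_cases: int
    feature_emission_prob: float


@dataclass
class VariantSpec:
    """A variant at Hardy-Weinberg frequency ``alt_allele_freq`` whose
    carriers' raw scores for ``linked_disease_id`` shift by effect_hom
    (homozygotes) / effect_het (heterozygotes), on the raw-score scale."""
    variant_id: str
    alt_allele_freq: float
    effect_hom: float = 0.0
    effect_het: float = 0.0
    linked_disease_id: str = ""


@dataclass
class SimulationConfig:
    n_persons: int = 5000
    seed: int = 0
    background_code_rate: float = 6.0
    disease_signal: list[DiseaseSignal] = field(default_factory=lambda: [
        DiseaseSignal("OMIM:219700", n_cases=50, feature_emission_prob=0.8)])
    variant_spec: list[VariantSpec] = field(default_factory=lambda: [
        VariantSpec("var_pathogenic", 0.05, effect_hom=2.0, effect_het=0.0,
                    linked_disease_id="OMIM:219700"),
        VariantSpec("var_benign", 0.20, effect_hom=0.0, effect_het=0.0,
                    linked_disease_id="OMIM:219700")])
    covariate_effects: dict = field(default_factory=lambda: {
        "sex": 0.2, "age": 0.5, "span": 0.3})

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValidationError("n_persons must be positive")
        if self.background_code_rate <= 0:
            raise ValidationError("background_code_rate must be positive")
        for sig in self.disease_signal:
            if sig.n_cases + max(2, sig.n_cases // 5) > self.n_persons:
                raise ValidationError(
                    f"disease {sig.disease_id}: n_cases={sig.n_cases} does not "
                    f"fit in n_persons={self.n_persons}")
            if not 0.0 <= sig.feature_emission_prob <= 1.0:
                raise ValidationError(
                    f"disease {sig.disease_id}: emission probability must be in [0, 1]")
        for vs in self.variant_spec:
            if not 0.0 < vs.alt_allele_freq < 1.0:
                raise ValidationError(
                    f"variant {vs.variant_id}: allele frequency must be in (0, 1)")
            if (vs.effect_hom or vs.effect_het) and not vs.linked_disease_id:
                raise ValidationError(
                    f"variant {vs.variant_id}: effect requires a linked disease")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["disease_signal"] = [DiseaseSignal(**d)
                                 for d in raw.get("disease_signal", [])] or None
        raw["variant_spec"] = [VariantSpec(**v)
                               for v in raw.get("variant_spec", [])] or None
        kwargs = {k: v for k, v in raw.items() if v is not None}
        return cls(**kwargs)


@dataclass
class SimulatedCohort:
    demographics: pd.DataFrame
    icd_occurrences: pd.DataFrame
    genotypes: pd.DataFrame
    truth: dict


def _random_days(rng, span_days: np.ndarray) -> np.ndarray:
    """Uniform day offset within each person's [0, span] window."""
    return (rng.random(len(span_days)) * (span_days + 1)).astype(int)


def simulate_cohort(config: SimulationConfig,
                    maps: BundledMaps | None = None) -> SimulatedCohort:
    """Generate one complete synthetic cohort plus its truth record."""
    config.validate()
    if maps is None:
        maps = load_bundled_maps()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    # --- demographics ------------------------------------------------------
    person_id = np.array([f"P{i + 1:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    age = rng.uniform(0.0, 90.0, n)
    span_years = np.maximum(rng.exponential(5.0, n), 30 / DAYS_PER_YEAR)
    span_days = np.maximum((span_years * DAYS_PER_YEAR).round().astype(int), 2)
    first = BASE_DATE + pd.to_timedelta(rng.integers(0, 3653, n), unit="D")
    last = first + pd.to_timedelta(span_days, unit="D")
    birth = first - pd.to_timedelta((age * DAYS_PER_YEAR).round().astype(int),
                                    unit="D")
    demos = pd.DataFrame({
        "person_id": person_id, "sex": sex,
        "first_visit_date": first.normalize(), "last_visit_date": last.normalize(),
        "birth_date": birth.normalize(),
        "age_first_visit": age,
    })

    # --- background ICD occurrences ---------------------------------------
    dx_pairs = set(zip(maps.disease_dx_icd["icd"], maps.disease_dx_icd["flag"]))
    pool = (maps.icd_phecode[["icd", "flag"]].drop_duplicates()
            .sort_values(["icd", "flag"]).reset_index(drop=True))
    pool = pool[[p not in dx_pairs for p in zip(pool["icd"], pool["flag"])]]
    feature_phecodes = set(maps.disease_phecode["phecode"])
    is_feature = maps.icd_phecode.set_index(["icd", "flag"])["phecode"].groupby(
        level=[0, 1]).apply(lambda s: s.isin(feature_phecodes).any())
    pool = pool.reset_index(drop=True)
    pool_weight = np.array([1.0 if is_feature.get(p, False) else 4.0
                            for p in zip(pool["icd"], pool["flag"])])
    # unmappable filler codes exercise the unmapped-code logging downstream
    pool = pd.concat([pool, pd.DataFrame({"icd": ["V70.0", "Z00.00"],
                                          "flag": [9, 10]})], ignore_index=True)
    pool_weight = np.append(pool_weight, [4.0, 4.0])
    pool_prob = pool_weight / pool_weight.sum()

    eff = config.covariate_effects
    z = (eff.get("sex", 0.0) * ((sex == "male").astype(float) - 0.5)
         + eff.get("age", 0.0) * (age / 90.0 - 0.5)
         + eff.get("span", 0.0) * (np.clip(span_years, 0, 20) / 10.0 - 0.5))
    lam = config.background_code_rate * np.exp(z)
    k = rng.poisson(lam)
    pidx = np.repeat(np.arange(n), k)
    code_idx = rng.choice(len(pool), size=int(k.sum()), p=pool_prob)
    frames = [pd.DataFrame({
        "person_id": person_id[pidx],
        "icd_code": pool["icd"].to_numpy()[code_idx],
        "flag": pool["flag"].to_numpy()[code_idx],
        "occurrence_date": first[pidx] + pd.to_timedelta(
            _random_days(rng, span_days[pidx]), unit="D"),
    })]

    # --- planted cases and 'neither' persons ------------------------------
    # emission sources per phecode, preferring ICD codes that map to exactly
    # one phecode so a planted emission moves only the intended indicator
    n_targets = maps.icd_phecode.groupby(["icd", "flag"])["phecode"].nunique()
    all_sources = (maps.icd_phecode.groupby("phecode")[["icd", "flag"]]
                   .apply(lambda g: list(zip(g["icd"], g["flag"]))).to_dict())
    sources = {j: ([c for c in codes if n_targets[c] == 1] or codes)
               for j, codes in all_sources.items()}
    dx_codes = (maps.disease_dx_icd.groupby("disease_id")[["icd", "flag"]]
                .apply(lambda g: list(zip(g["icd"], g["flag"]))).to_dict())
    disease_phecodes = (maps.disease_phecode.groupby("disease_id")["phecode"]
                        .apply(lambda s: sorted(s.unique())).to_dict())

    truth: dict = {"seed": config.seed, "n_persons": n,
                   "cases": {}, "neither": {}, "variants": {}}
    for sig in config.disease_signal:
        if sig.disease_id not in disease_phecodes:
            raise ValidationError(f"disease {sig.disease_id} not in disease map")
        n_neither = max(2, sig.n_cases // 5)
        chosen = rng.choice(n, size=sig.n_cases + n_neither, replace=False)
        case_idx, neither_idx = chosen[:sig.n_cases], chosen[sig.n_cases:]
        truth["cases"][sig.disease_id] = sorted(person_id[case_idx])
        truth["neither"][sig.disease_id] = sorted(person_id[neither_idx])

        rows = []
        for j in disease_phecodes[sig.disease_id]:
            emit = rng.random(sig.n_cases) < sig.feature_emission_prob
            for i in case_idx[emit]:
                icd_code, flag = sources[j][rng.integers(len(sources[j]))]
                day = int(rng.integers(0, span_days[i] + 1))
                rows.append((person_id[i], icd_code, flag, day, i))
        codes = dx_codes.get(sig.disease_id)
        if not codes:
            raise ValidationError(f"disease {sig.disease_id} has no diagnostic codes")
        for i in case_idx:  # diagnostic code on two distinct dates
            d1, d2 = rng.choice(span_days[i] + 1, size=2, replace=False)
            for day in (int(d1), int(d2)):
                icd_code, flag = codes[rng.integers(len(codes))]
                rows.append((person_id[i], icd_code, flag, day, i))
        for i in neither_idx:  # single-date posting -> 'neither'
            icd_code, flag = codes[rng.integers(len(codes))]
            rows.append((person_id[i], icd_code, flag,
                         int(rng.integers(0, span_days[i] + 1)), i))
        frames.append(_with_dates(rows, first))

    # --- genotypes at Hardy-Weinberg --------------------------------------
    geno_frames = []
    allele_counts = {}
    for vs in config.variant_spec:
        counts = rng.binomial(2, vs.alt_allele_freq, n)
        allele_counts[vs.variant_id] = counts
        geno_frames.append(pd.DataFrame({
            "person_id": person_id, "variant_id": vs.variant_id,
            "allele_count": pd.array(counts, dtype="Int64")}))

    # --- score-calibrated carrier boosts -----------------------------------
    icd_df = _canonical_icd(pd.concat(frames, ignore_index=True))
    needs_boost = [vs for vs in config.variant_spec
                   if vs.effect_hom != 0.0 or vs.effect_het != 0.0]
    if needs_boost:
        phe = map_icd_to_phecodes(icd_df, maps.icd_phecode)
        wt = calc_weights(demos, phe).set_index("phecode")["weight"]
        has = set(zip(phe["person_id"], phe["phecode"]))
        for vs in needs_boost:
            phecodes = disease_phecodes.get(vs.linked_disease_id)
            if phecodes is None:
                raise ValidationError(
                    f"variant {vs.variant_id}: linked disease "
                    f"{vs.linked_disease_id!r} not in disease map")
            counts = allele_counts[vs.variant_id]
            shifts = {"hom": [], "het": []}
            rows = []
            for group, effect, label in ((counts == 2, vs.effect_hom, "hom"),
                                         (counts == 1, vs.effect_het, "het")):
                if effect == 0.0:
                    continue
                for i in np.where(group)[0]:
                    lacking = [j for j in phecodes
                               if (person_id[i], j) not in has and j in wt.index]
                    lacking.sort(key=lambda j: (-wt[j], j))
                    S = float(sum(wt[j] for j in lacking))
                    if S <= 0.0:
                        shifts[label].append(0.0)
                        continue
                    # greedy fill up to the target, then a single Bernoulli
                    # top-up so the expected shift is exactly the effect with
                    # minimal carrier-level variance
                    emit, filled = [], 0.0
                    for j in lacking:
                        if filled + wt[j] <= effect + 1e-12:
                            emit.append(j)
                            filled += wt[j]
                    if filled < effect and len(emit) < len(lacking):
                        rest = [j for j in lacking if j not in emit]
                        top_up = min(rest, key=lambda j: (wt[j], j))
                        p_top = (effect - filled) / wt[top_up]
                        if rng.random() < p_top:
                            emit.append(top_up)
                        filled += p_top * wt[top_up]
                    shifts[label].append(filled)  # = min(effect, S)
                    for j in emit:
                        icd_code, flag = sources[j][rng.integers(len(sources[j]))]
                        rows.append((person_id[i], icd_code, flag,
                                     int(rng.integers(0, span_days[i] + 1)), i))
            if rows:
                frames.append(_with_dates(rows, first))
            truth["variants"][vs.variant_id] = {
                "spec": asdict(vs),
                "n_hom_alt": int((counts == 2).sum()),
                "n_het": int((counts == 1).sum()),
                "expected_shift_hom": (float(np.mean(shifts["hom"]))
                                       if shifts["hom"] else 0.0),
                "expected_shift_het": (float(np.mean(shifts["het"]))
                                       if shifts["het"] else 0.0),
            }
        icd_df = _canonical_icd(pd.concat(frames, ignore_index=True))
    for vs in config.variant_spec:
        truth["variants"].setdefault(vs.variant_id, {
            "spec": asdict(vs),
            "n_hom_alt": int((allele_counts[vs.variant_id] == 2).sum()),
            "n_het": int((allele_counts[vs.variant_id] == 1).sum()),
            "expected_shift_hom": 0.0, "expected_shift_het": 0.0})

    if geno_frames:
        genotypes = (pd.concat(geno_frames, ignore_index=True)
                     .sort_values(["person_id", "variant_id"], kind="mergesort")
                     .reset_index(drop=True))
    else:
        genotypes = pd.DataFrame({"person_id": pd.Series([], dtype=str),
                                  "variant_id": pd.Series([], dtype=str),
                                  "allele_count": pd.array([], dtype="Int64")})
    logger.info("simulate_cohort: %d person(s), %d ICD occurrence(s), "
                "%d variant(s)", n, len(icd_df), len(config.variant_spec))
    return SimulatedCohort(demos, icd_df, genotypes, truth)


def _with_dates(rows: list[tuple], first) -> pd.DataFrame:
    """Turn (person_id, icd, flag, day-offset, person-index) tuples into an
    occurrence frame, resolving each day offset against the person's window."""
    df = pd.DataFrame(rows, columns=["person_id", "icd_code", "flag", "day", "i"])
    base = first.to_numpy()[df["i"].to_numpy()]
    df["occurrence_date"] = base + df["day"].to_numpy().astype("timedelta64[D]")
    return df.drop(columns=["day", "i"])


def _canonical_icd(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["occurrence_date"] = pd.to_datetime(df["occurrence_date"]).dt.normalize()
    df["flag"] = df["flag"].astype("int64")
    return (df.drop_duplicates(subset=["person_id", "icd_code", "flag",
                                       "occurrence_date"])
            .sort_values(["person_id", "icd_code", "flag", "occurrence_date"],
                         kind="mergesort")
            .reset_index(drop=True))
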