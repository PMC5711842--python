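"""Synthetic screen generator with planted ground truth.

Emulates the statistical structure the analysis pipeline assumes: a
compound library with a mixture of activity classes, all-or-nothing dose
activation above a per-compound concentration threshold, toxicity (general
morphology defects and lethality) rising with concentration, genotype
modifiers (her1 enhancement, hes6 suppression of segmentation severity),
and two wild-type replicates differing only through noise.

Ordinal scores arise from a latent-Gaussian cut-point model: each engaged
parameter carries a nonnegative latent severity; per-embryo scores are the
latent plus Gaussian noise discretized at three increasing cut-points and
clamped to [0, 3]; the well score is the consensus over embryos.  With
noise_sd = 0 the whole generator is deterministic, which gives an exact
recovery oracle for downstream hit calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, ValidationError
from .model import (
    DEFAULT_SCHEMA,
    EXPERIMENTS,
    WILD_TYPE_EXPERIMENTS,
    ParameterSchema,
    PhenotypicVector,
    ScreenTable,
    TreatmentRecord,
    consensus_scores,
    format_concentration,
)
from .ranking import (
    DEFAULT_RANKING_CONFIG,
    RankingConfig,
    direct_seg_predicate,
    summarize_treatment,
)

COMPOUND_CLASSES = (
    "inactive",
    "direct_seg",
    "seg_plus_morph",
    "morph_only",
    "secondary_tail",
    "toxic",
)

DEFAULT_CLASS_PROPORTIONS = {
    "inactive": 0.58,
    "direct_seg": 0.12,
    "seg_plus_morph": 0.10,
    "morph_only": 0.10,
    "secondary_tail": 0.02,
    "toxic": 0.08,
}

GENOTYPE_TAGS = ("none", "her1_only", "her1_enhanced", "hes6_suppressed")


@dataclass(frozen=True)
class SimConfig:
    n_compounds: int = 243
    concentrations: Tuple[float, ...] = (2.0, 10.0, 50.0)
    experiments: Tuple[str, ...] = EXPERIMENTS
    class_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    noise_sd: float = 0.3
    score_cutpoints: Tuple[float, float, float] = (0.5, 1.5, 2.5)
    lethality_scale: float = 0.25
    n_embryos_per_well: int = 5
    consensus_min_embryos: int = 3
    #: systematic latent shift added to every wt_B parameter, for
    #: stress-testing the reproducibility filter; 0 = pure noise replicates
    batch_shift: float = 0.0
    #: fractions of direct_seg compounds given each genotype behavior
    her1_only_fraction: float = 0.2
    her1_enhanced_fraction: float = 0.15
    hes6_suppressed_fraction: float = 0.3
    #: fraction of (multi-concentration) direct_seg compounds whose top
    #: concentration is masked by toxicity-level morphology defects
    masked_top_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations",
            tuple(sorted(float(c) for c in self.concentrations)),
        )
        object.__setattr__(self, "experiments", tuple(self.experiments))
        object.__setattr__(
            self, "score_cutpoints", tuple(float(c) for c in self.score_cutpoints)
        )
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be >= 1")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("class_proportions must sum to 1")
        unknown = set(self.class_proportions) - set(COMPOUND_CLASSES)
        if unknown:
            raise ConfigError(f"unknown compound classes: {sorted(unknown)}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigError("class proportions must be >= 0")
        cps = self.score_cutpoints
        if not all(cps[i] < cps[i + 1] for i in range(len(cps) - 1)):
            raise ConfigError("score_cutpoints must be strictly increasing")
        if self.noise_sd < 0 or self.lethality_scale < 0:
            raise ConfigError("noise_sd and lethality_scale must be >= 0")
        if self.n_embryos_per_well < 1:
            raise ConfigError("n_embryos_per_well must be >= 1")
        fr = (
            self.her1_only_fraction
            + self.her1_enhanced_fraction
            + self.hes6_suppressed_fraction
        )
        if fr > 1.0 + 1e-9:
            raise ConfigError("genotype-tag fractions must sum to <= 1")

    def activity_threshold_candidates(self) -> Tuple[float, ...]:
        """Dose thresholds placed below each screened concentration, so a
        compound with the i-th threshold is active at concentrations i..max."""
        concs = self.concentrations
        cands = [concs[0] / 2.0]
        cands.extend(
            (concs[i - 1] + concs[i]) / 2.0 for i in range(1, len(concs))
        )
        return tuple(cands)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass(frozen=True)
class CompoundProfile:
    compound_id: str
    compound_class: str
    activity_threshold: float = math.inf
    toxicity_threshold: float = math.inf
    seg_effect: float = 0.0
    morph_effect: float = 0.0
    her1_multiplier: float = 1.0
    hes6_multiplier: float = 1.0
    #: which segmentation codes the compound engages
    seg_pattern: Tuple[str, ...] = ()
    #: per-code severity weights aligned with seg_pattern (default: all 1)
    seg_weights: Tuple[float, ...] = ()
    #: which morphology codes the toxicity component engages
    morph_pattern: Tuple[str, ...] = DEFAULT_SCHEMA.morphology_codes
    genotype_tag: str = "none"

    def __post_init__(self) -> None:
        if not self.seg_weights:
            object.__setattr__(
                self, "seg_weights", tuple(1.0 for _ in self.seg_pattern)
            )
        if len(self.seg_weights) != len(self.seg_pattern):
            raise ValidationError("seg_weights must align with seg_pattern")
        if any(w < 0 for w in self.seg_weights):
            raise ValidationError("seg_weights must be >= 0")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValidationError(
                f"unknown compound class {self.compound_class!r}"
            )
        if self.seg_effect < 0 or self.morph_effect < 0:
            raise ValidationError("effect sizes must be >= 0")
        if self.her1_multiplier < 0 or self.hes6_multiplier < 0:
            raise ValidationError("genotype multipliers must be >= 0")
        if self.compound_class == "inactive" and (
            self.seg_effect or self.morph_effect
        ):
            raise ValidationError("inactive compounds must have zero effects")


def genotype_multiplier(profile: CompoundProfile, experiment: str) -> float:
    if experiment in WILD_TYPE_EXPERIMENTS:
        return 1.0
    if experiment == "her1":
        return profile.her1_multiplier
    if experiment == "hes6":
        return profile.hes6_multiplier
    raise ValidationError(f"unknown experiment {experiment!r}")


def latent_severities(
    profile: CompoundProfile, concentration: float, experiment: str
) -> Tuple[float, float]:
    """(segmentation, morphology) latent severity for one treatment:
    step dose activation above the respective threshold, genotype multiplier
    on the segmentation component only."""
    seg = (
        profile.seg_effect * genotype_multiplier(profile, experiment)
        if concentration >= profile.activity_threshold
        else 0.0
    )
    morph = (
        profile.morph_effect
        if concentration >= profile.toxicity_threshold
        else 0.0
    )
    return seg, morph


def _latent_parameter_vector(
    profile: CompoundProfile,
    concentration: float,
    experiment: str,
    config: SimConfig,
    schema: ParameterSchema,
) -> np.ndarray:
    seg, morph = latent_severities(profile, concentration, experiment)
    weight = dict(zip(profile.seg_pattern, profile.seg_weights))
    latents = np.zeros(schema.n_parameters)
    for i, code in enumerate(schema.codes):
        if code in profile.morph_pattern and code in schema.morphology_codes:
            latents[i] = morph
        elif code in weight:
            latents[i] = seg * weight[code]
    if experiment == "wt_B":
        latents = latents + config.batch_shift
    return latents


def discretize(latents: np.ndarray, cutpoints: Sequence[float]) -> np.ndarray:
    """Map latent severities to ordinal scores: count of cut-points at or
    below the latent, clamped to [0, len(cutpoints)]."""
    return np.digitize(latents, list(cutpoints), right=False)


def lethality_probability(morph_burden: float, scale: float) -> float:
    """P(lethal) = 1 - exp(-scale * morphology burden): zero for unaffected
    embryos, saturating toward 1 with increasing toxic burden."""
    return 1.0 - math.exp(-scale * max(morph_burden, 0.0))


def morphology_burden(
    profile: CompoundProfile,
    concentration: float,
    schema: ParameterSchema = DEFAULT_SCHEMA,
) -> float:
    """Mean morphology latent over all 6 codes — the toxic load driving
    lethality.  A compound deforming a single structure (e.g. tail shape)
    is far less often lethal than one with body-wide defects."""
    _, morph = latent_severities(profile, concentration, "wt_A")
    engaged = sum(
        1 for c in profile.morph_pattern if c in schema.morphology_codes
    )
    return morph * engaged / len(schema.morphology_codes)


def noise_free_vector(
    profile: CompoundProfile,
    concentration: float,
    experiment: str,
    config: SimConfig,
    schema: ParameterSchema = DEFAULT_SCHEMA,
) -> PhenotypicVector:
    """The deterministic well vector the generator produces at noise_sd = 0."""
    latents = _latent_parameter_vector(
        profile, concentration, experiment, config, schema
    )
    scores = discretize(latents, config.score_cutpoints)
    scores = np.clip(scores, 0, schema.max_score)
    return PhenotypicVector(tuple(int(s) for s in scores), schema)


# ---------------------------------------------------------------------------
# Profile drawing
# ---------------------------------------------------------------------------

def _draw_direct_seg(
    compound_id: str, config: SimConfig, rng: np.random.Generator
) -> CompoundProfile:
    c1 = config.score_cutpoints[0]
    c2 = config.score_cutpoints[1]
    c3 = config.score_cutpoints[2]
    cands = config.activity_threshold_candidates()
    activity = float(rng.choice(cands))

    u = rng.random()
    if u < config.her1_only_fraction:
        tag = "her1_only"
    elif u < config.her1_only_fraction + config.her1_enhanced_fraction:
        tag = "her1_enhanced"
    elif u < (
        config.her1_only_fraction
        + config.her1_enhanced_fraction
        + config.hes6_suppressed_fraction
    ):
        tag = "hes6_suppressed"
    else:
        tag = "none"

    her1_mult = 1.0
    hes6_mult = 1.0
    if tag == "her1_only":
        # sub-threshold in wild type, amplified well past threshold in her1
        seg = rng.uniform(0.3 * c1, 0.7 * c1)
        her1_mult = rng.uniform(2.4 * c1, 2.0 * c2) / seg
    elif tag == "her1_enhanced":
        # mild in wild type, at least one score level higher in her1
        seg = rng.uniform(1.2 * c1, 0.85 * c2)
        her1_mult = rng.uniform(0.95 * c3, 1.2 * c3) / seg
    elif tag == "hes6_suppressed":
        seg = rng.uniform(c3 + 0.2, c3 + 0.6)
        hes6_mult = rng.uniform(0.0, 0.5 * c1) / seg
    else:
        seg = rng.uniform(c3 + 0.2, c3 + 0.6)

    # engaged segmentation codes: boundary defects plus further codes.
    # Breadth scales with severity (strong compounds disrupt more axial
    # positions); genotype-dependent compounds that are weak in wild type
    # stay narrow so their sub-threshold phenotypes remain focal.
    extra_pool = ["AD", "TD", "PD", "BS", "S"]
    if tag in ("her1_only", "her1_enhanced"):
        k = 1
    else:
        k = int(rng.integers(2, 6))
    extras = sorted(rng.choice(extra_pool, size=k, replace=False).tolist())
    pattern = tuple(["BD"] + extras)
    weights = tuple(float(w) for w in rng.uniform(0.85, 1.0, size=len(pattern)))

    morph = float(rng.uniform(0.0, 0.3 * c1))
    toxicity = 0.0
    masked = (
        activity < cands[-1]
        and rng.random() < config.masked_top_fraction
    )
    if masked:
        # general-morphology defects appear at the top concentration,
        # pushing the morphology mean past the hit predicate's cap there
        toxicity = cands[-1]
        morph = float(rng.uniform(c3 + 0.15, c3 + 0.9))
    return CompoundProfile(
        compound_id=compound_id,
        compound_class="direct_seg",
        activity_threshold=activity,
        toxicity_threshold=toxicity if masked else (0.0 if morph > 0 else math.inf),
        seg_effect=float(seg),
        morph_effect=morph,
        her1_multiplier=float(her1_mult),
        hes6_multiplier=float(hes6_mult),
        seg_pattern=pattern,
        seg_weights=weights,
        morph_pattern=DEFAULT_SCHEMA.morphology_codes,
        genotype_tag=tag,
    )


def _draw_profile(
    compound_id: str,
    compound_class: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> CompoundProfile:
    c1, c2, c3 = config.score_cutpoints
    cands = config.activity_threshold_candidates()
    if compound_class == "inactive":
        return CompoundProfile(compound_id, "inactive")
    if compound_class == "direct_seg":
        return _draw_direct_seg(compound_id, config, rng)
    if compound_class == "secondary_tail":
        # strong secondary-tail signal (S, BS) dominating a milder
        # tail-shape defect, so the hit predicate holds with margin
        thr = float(rng.choice(cands))
        return CompoundProfile(
            compound_id,
            "secondary_tail",
            activity_threshold=thr,
            toxicity_threshold=thr,
            seg_effect=float(rng.uniform(c3 + 0.1, c3 + 0.6)),
            morph_effect=float(rng.uniform(1.15 * c2, 0.9 * c3)),
            seg_pattern=("S", "BS", "TD", "PD"),
            seg_weights=(1.0, 1.0, 0.75, 0.75),
            morph_pattern=("T",),
        )
    if compound_class == "seg_plus_morph":
        # segmentation defects buried under saturating general-morphology
        # defects, keeping the treatment safely past the toxicity cap
        thr = float(rng.choice(cands))
        pool = ["BD", "AD", "TD", "PD"]
        k = int(rng.integers(3, 5))
        pattern = tuple(sorted(rng.choice(pool, size=k, replace=False).tolist()))
        return CompoundProfile(
            compound_id,
            "seg_plus_morph",
            activity_threshold=thr,
            toxicity_threshold=thr,
            seg_effect=float(rng.uniform(1.15 * c2, c3 + 0.2)),
            morph_effect=float(rng.uniform(c3 + 0.15, c3 + 0.9)),
            seg_pattern=pattern,
        )
    if compound_class == "morph_only":
        thr = float(rng.choice(cands[:2])) if len(cands) > 1 else cands[0]
        return CompoundProfile(
            compound_id,
            "morph_only",
            activity_threshold=math.inf,
            toxicity_threshold=thr,
            morph_effect=float(rng.uniform(c1 + 0.2, c2 + 0.5)),
        )
    if compound_class == "toxic":
        return CompoundProfile(
            compound_id,
            "toxic",
            activity_threshold=math.inf,
            toxicity_threshold=float(rng.choice(cands)),
            morph_effect=float(rng.uniform(0.95 * c3, c3 + 1.0)),
        )
    raise ConfigError(f"unknown compound class {compound_class!r}")


def draw_compound_profiles(
    config: SimConfig, rng: np.random.Generator
) -> List[CompoundProfile]:
    """Draw the compound library: classes from the configured mixture, then
    class-specific effect sizes, dose thresholds and genotype multipliers."""
    classes = [c for c in COMPOUND_CLASSES if config.class_proportions.get(c, 0) > 0]
    probs = np.array([config.class_proportions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    width = max(4, len(str(config.n_compounds)))
    drawn = rng.choice(len(classes), size=config.n_compounds, p=probs)
    return [
        _draw_profile(f"C{i:0{width}d}", classes[int(ci)], config, rng)
        for i, ci in enumerate(drawn)
    ]


# ---------------------------------------------------------------------------
# Treatment and screen simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentRecord:
    seg_latent: float
    morph_latent: float
    lethal_p: float
    lethal: bool


def simulate_treatment(
    profile: CompoundProfile,
    concentration: float,
    experiment: str,
    config: SimConfig,
    rng: np.random.Generator,
    plate: str = "",
    well: str = "",
    schema: ParameterSchema = DEFAULT_SCHEMA,
) -> Tuple[TreatmentRecord, LatentRecord]:
    """Simulate one well: lethality draw, per-embryo noisy ordinal scores,
    consensus well vector."""
    if float(concentration) not in config.concentrations:
        raise ConfigError(
            f"concentration {concentration} not in screened set "
            f"{config.concentrations}"
        )
    if experiment not in config.experiments:
        raise ValidationError(f"unknown experiment {experiment!r}")
    seg_latent, morph_latent = latent_severities(
        profile, float(concentration), experiment
    )
    burden = morphology_burden(profile, float(concentration), schema)
    p_lethal = lethality_probability(burden, config.lethality_scale)
    lethal = bool(rng.random() < p_lethal)
    latent_rec = LatentRecord(
        seg_latent=seg_latent,
        morph_latent=morph_latent,
        lethal_p=p_lethal,
        lethal=lethal,
    )
    n = config.n_embryos_per_well
    if lethal:
        record = TreatmentRecord(
            compound_id=profile.compound_id,
            concentration=float(concentration),
            experiment=experiment,
            plate=plate,
            well=well,
            lethal=True,
            n_embryos=n,
            n_scoreable=0,
            vector=None,
        )
        return record, latent_rec

    latents = _latent_parameter_vector(
        profile, float(concentration), experiment, config, schema
    )
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=(n, schema.n_parameters))
    else:
        noise = np.zeros((n, schema.n_parameters))
    embryo_scores = discretize(latents[None, :] + noise, config.score_cutpoints)
    embryo_scores = np.clip(embryo_scores, 0, schema.max_score)
    support = (
        config.consensus_min_embryos
        if n >= config.consensus_min_embryos
        else math.ceil(0.6 * n)
    )
    consensus = consensus_scores(embryo_scores, support)
    record = TreatmentRecord(
        compound_id=profile.compound_id,
        concentration=float(concentration),
        experiment=experiment,
        plate=plate,
        well=well,
        lethal=False,
        n_embryos=n,
        n_scoreable=n,
        vector=PhenotypicVector(tuple(int(s) for s in consensus), schema),
    )
    return record, latent_rec


@dataclass
class GroundTruth:
    """Planted compound profiles plus per-treatment latent state, aligned
    with the simulated ScreenTable."""

    config: SimConfig
    profiles: Dict[str, CompoundProfile]
    #: {(compound_id, concentration, experiment): LatentRecord}
    treatments: Dict[Tuple[str, float, str], LatentRecord]

    def compounds_with_tag(self, tag: str) -> List[str]:
        return sorted(
            cid for cid, p in self.profiles.items() if p.genotype_tag == tag
        )

    def compounds_of_class(self, compound_class: str) -> List[str]:
        return sorted(
            cid
            for cid, p in self.profiles.items()
            if p.compound_class == compound_class
        )

    def expected_qualifying(
        self,
        compound_id: str,
        ranking_config: RankingConfig = DEFAULT_RANKING_CONFIG,
    ) -> List[Tuple[float, str]]:
        """(concentration, experiment) cells where the noise-free generator
        output satisfies the direct-segmentation predicate."""
        profile = self.profiles[compound_id]
        out = []
        for conc in self.config.concentrations:
            for exp in self.config.experiments:
                vec = noise_free_vector(profile, conc, exp, self.config)
                if direct_seg_predicate(summarize_treatment(vec), ranking_config):
                    out.append((conc, exp))
        return out

    def expected_hits(
        self, ranking_config: RankingConfig = DEFAULT_RANKING_CONFIG
    ) -> set:
        """Compounds a perfect (noise-free) analysis would call as hits,
        including the single-wild-type-replicate exclusion."""
        wt = set(WILD_TYPE_EXPERIMENTS)
        hits = set()
        for cid in self.profiles:
            quals = self.expected_qualifying(cid, ranking_config)
            if not quals:
                continue
            exps = {e for _, e in quals}
            if exps == {"wt_A"} or exps == {"wt_B"}:
                continue
            hits.add(cid)
        return hits

    def save(self, path) -> None:
        """Companion TSV: one row per treatment with class, tag and latents."""
        path = Path(path)
        header = [
            "compound_id", "concentration_uM", "experiment", "compound_class",
            "genotype_tag", "seg_latent", "morph_latent", "lethal_p", "lethal",
        ]
        lines = ["\t".join(header)]
        for (cid, conc, exp), lat in sorted(self.treatments.items()):
            p = self.profiles[cid]
            lines.append(
                "\t".join(
                    [
                        cid,
                        format_concentration(conc),
                        exp,
                        p.compound_class,
                        p.genotype_tag,
                        f"{lat.seg_latent:.6g}",
                        f"{lat.morph_latent:.6g}",
                        f"{lat.lethal_p:.6g}",
                        "1" if lat.lethal else "0",
                    ]
                )
            )
        path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def simulate_screen(
    config: SimConfig, schema: ParameterSchema = DEFAULT_SCHEMA
) -> Tuple[ScreenTable, GroundTruth]:
    """Simulate the full factorial screen
    (n_compounds x concentrations x experiments); deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    profiles = draw_compound_profiles(config, rng)
    records: List[TreatmentRecord] = []
    latents: Dict[Tuple[str, float, str], LatentRecord] = {}
    n_wells_per_plate = 96
    i_well = 0
    for profile in profiles:
        for conc in config.concentrations:
            for exp in config.experiments:
                plate = f"P{i_well // n_wells_per_plate + 1:03d}"
                well = (
                    f"{chr(ord('A') + (i_well % n_wells_per_plate) // 12)}"
                    f"{(i_well % 12) + 1:02d}"
                )
                rec, lat = simulate_treatment(
                    profile, conc, exp, config, rng,
                    plate=plate, well=well, schema=schema,
                )
                records.append(rec)
                latents[(profile.compound_id, float(conc), exp)] = lat
                i_well += 1
    table = ScreenTable(records=tuple(records), schema=schema)
    truth = GroundTruth(
        config=config,
        profiles={p.compound_id: p for p in profiles},
        treatments=latents,
    )
    return table, truth


def profiles_to_tsv(profiles: Sequence[CompoundProfile], path) -> None:
    """Write the compound library (one row per compound) as TSV."""
    path = Path(path)
    fields = [
        "compound_id", "compound_class", "activity_threshold",
        "toxicity_threshold", "seg_effect", "morph_effect",
        "her1_multiplier", "hes6_multiplier", "seg_pattern",
        "seg_weights", "morph_pattern", "genotype_tag",
    ]
    lines = ["\t".join(fields)]
    for p in profiles:
        d = asdict(p)
        d["seg_pattern"] = ",".join(p.seg_pattern)
        d["seg_weights"] = ",".join(f"{w:.6g}" for w in p.seg_weights)
        d["morph_pattern"] = ",".join(p.morph_pattern)
        lines.append("\t".join(str(d[f]) for f in fields))
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
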