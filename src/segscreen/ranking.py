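"""Hit selection: treatment summaries, SSMD and mean-difference rankings,
the direct-segmentation predicate, compound-level hit calling with the
wild-type reproducibility filter, and genotype / concentration profiling.

The SSMD of a treatment contrasts the segmentation half of its phenotypic
vector against the general-morphology half:

    ssmd = (seg_mean - morph_mean) / sqrt(seg_var + morph_var)

with sample variances (n-1 denominator, n=6 per half).  When both variances
vanish the statistic is 0 for a zero numerator and signed infinity otherwise,
so rankings remain total and deterministic.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from scipy import stats

from .errors import ConfigError, InsufficientDataError, ValidationError
from .model import (
    DEFAULT_SCHEMA,
    ParameterSchema,
    PhenotypicVector,
    ScreenTable,
    TreatmentRecord,
    WILD_TYPE_EXPERIMENTS,
    _experiment_sort_key,
)

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = (
    "wild_type_supported",
    "her1_only",
    "her1_enhanced",
    "hes6_suppressed",
    "mixed",
)


@dataclass(frozen=True)
class RankingConfig:
    ssmd_exclude_seg_mean_below: float = 0.2
    ssmd_exclude_morph_mean_above: float = 2.0
    #: "union": exclude if either condition holds (default); "conjunction":
    #: exclude only when both hold.
    ssmd_exclusion_rule: str = "union"
    meandiff_morph_max: float = 2.0
    predicate_min_seg_mean: float = 0.2
    predicate_morph_max: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "ssmd_exclude_seg_mean_below",
            "ssmd_exclude_morph_mean_above",
            "meandiff_morph_max",
            "predicate_min_seg_mean",
            "predicate_morph_max",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.ssmd_exclusion_rule not in ("union", "conjunction"):
            raise ConfigError("ssmd_exclusion_rule must be union or conjunction")


DEFAULT_RANKING_CONFIG = RankingConfig()


@dataclass(frozen=True)
class TreatmentSummary:
    seg_mean: float
    morph_mean: float
    seg_var: float
    morph_var: float
    ssmd: float
    mean_diff: float


def summarize_treatment(
    vector: PhenotypicVector, schema: Optional[ParameterSchema] = None
) -> TreatmentSummary:
    """Means, sample variances and the two ranking statistics of one vector."""
    schema = schema or vector.schema
    if len(vector.scores) != schema.n_parameters:
        raise ValidationError(
            f"vector has {len(vector.scores)} scores, "
            f"expected {schema.n_parameters}"
        )
    seg = [float(s) for s in vector.segmentation_scores]
    morph = [float(s) for s in vector.morphology_scores]
    seg_mean = statistics.fmean(seg)
    morph_mean = statistics.fmean(morph)
    seg_var = statistics.variance(seg)
    morph_var = statistics.variance(morph)
    diff = seg_mean - morph_mean
    denom = math.sqrt(seg_var + morph_var)
    if denom == 0.0:
        ssmd = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        ssmd = diff / denom
    return TreatmentSummary(
        seg_mean=seg_mean,
        morph_mean=morph_mean,
        seg_var=seg_var,
        morph_var=morph_var,
        ssmd=ssmd,
        mean_diff=diff,
    )


@dataclass
class Ranking:
    """An ordered list of (record, summary) plus the exclusion log."""

    entries: List[Tuple[TreatmentRecord, TreatmentSummary]]
    excluded: List[Tuple[TreatmentRecord, str]] = field(default_factory=list)
    method: str = ""

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    def treatment_keys(self) -> List[tuple]:
        return [rec.key for rec, _ in self.entries]


def _record_tiebreak(record: TreatmentRecord) -> tuple:
    return (
        record.compound_id,
        record.concentration,
        _experiment_sort_key(record.experiment),
    )


def _summarized(table: ScreenTable):
    for rec in table.analyzable_records():
        yield rec, summarize_treatment(rec.vector, table.schema)


def rank_by_ssmd(
    table: ScreenTable, config: RankingConfig = DEFAULT_RANKING_CONFIG
) -> Ranking:
    """Sort analyzable treatments by SSMD (descending) after exclusions.

    A treatment is excluded when its segmentation mean is below the low-signal
    threshold or its morphology mean exceeds the toxicity threshold (union
    reading; the conjunction reading is available via the config).
    Ties break by mean difference descending, then by (compound,
    concentration, experiment).
    """
    kept, excluded = [], []
    for rec, summ in _summarized(table):
        low_seg = summ.seg_mean < config.ssmd_exclude_seg_mean_below
        high_morph = summ.morph_mean > config.ssmd_exclude_morph_mean_above
        reasons = []
        if low_seg:
            reasons.append(
                f"seg_mean {summ.seg_mean:.4g} below "
                f"{config.ssmd_exclude_seg_mean_below}"
            )
        if high_morph:
            reasons.append(
                f"morph_mean {summ.morph_mean:.4g} above "
                f"{config.ssmd_exclude_morph_mean_above}"
            )
        if config.ssmd_exclusion_rule == "union":
            drop = low_seg or high_morph
        else:
            drop = low_seg and high_morph
        if drop:
            excluded.append((rec, "; ".join(reasons)))
        else:
            kept.append((rec, summ))
    if excluded:
        logger.info("rank_by_ssmd: excluded %d treatments", len(excluded))
    kept.sort(
        key=lambda e: (-e[1].ssmd, -e[1].mean_diff, _record_tiebreak(e[0]))
    )
    return Ranking(entries=kept, excluded=excluded, method="ssmd")


def rank_by_mean_diff(
    table: ScreenTable, config: RankingConfig = DEFAULT_RANKING_CONFIG
) -> Ranking:
    """Sort treatments with morph_mean strictly below the cap and a strictly
    positive mean difference, by mean difference descending."""
    kept, excluded = [], []
    for rec, summ in _summarized(table):
        if summ.morph_mean >= config.meandiff_morph_max:
            excluded.append(
                (rec, f"morph_mean {summ.morph_mean:.4g} not below "
                      f"{config.meandiff_morph_max}")
            )
        elif summ.mean_diff <= 0:
            excluded.append(
                (rec, f"mean_diff {summ.mean_diff:.4g} not positive")
            )
        else:
            kept.append((rec, summ))
    kept.sort(key=lambda e: (-e[1].mean_diff, _record_tiebreak(e[0])))
    return Ranking(entries=kept, excluded=excluded, method="mean_diff")


def ranking_concordance(rank_a: Ranking, rank_b: Ranking) -> Tuple[float, int]:
    """Spearman rank correlation of the two orderings over their common
    treatments; returns (rho, n_common)."""
    if not len(rank_a) or not len(rank_b):
        raise InsufficientDataError("both rankings must be nonempty")
    pos_a = {key: i for i, key in enumerate(rank_a.treatment_keys())}
    pos_b = {key: i for i, key in enumerate(rank_b.treatment_keys())}
    common = sorted(set(pos_a) & set(pos_b))
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >= 3 common treatments, got {len(common)}"
        )
    xs = [pos_a[k] for k in common]
    ys = [pos_b[k] for k in common]
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho), len(common)


def direct_seg_predicate(
    summary: TreatmentSummary, config: RankingConfig = DEFAULT_RANKING_CONFIG
) -> bool:
    """True iff the treatment shows a direct segmentation phenotype:
    meaningful segmentation signal with sub-toxic morphology."""
    return (
        summary.morph_mean < config.predicate_morph_max
        and summary.mean_diff > 0
        and summary.seg_mean >= config.predicate_min_seg_mean
    )


@dataclass
class HitCall:
    compound_id: str
    is_hit: bool
    qualifying_treatments: List[Tuple[float, str]]
    excluded_as_irreproducible: bool
    genotype_class: str
    active_concentrations: Tuple[float, ...]
    single_concentration: bool
    best_ssmd: Optional[float] = None
    best_mean_diff: Optional[float] = None


def _qualifying_by_compound(
    table: ScreenTable, config: RankingConfig
) -> Tuple[Dict[str, list], Dict[str, dict]]:
    """Per compound: qualifying (conc, experiment) list, and all summaries
    keyed by (conc, experiment)."""
    qualifying: Dict[str, list] = {c: [] for c in table.compounds}
    summaries: Dict[str, dict] = {c: {} for c in table.compounds}
    for rec, summ in _summarized(table):
        summaries[rec.compound_id][(rec.concentration, rec.experiment)] = summ
        if direct_seg_predicate(summ, config):
            qualifying[rec.compound_id].append((rec.concentration, rec.experiment))
    return qualifying, summaries


def _classify_genotype(
    qualifying: Sequence[Tuple[float, str]],
    summaries: Dict[tuple, TreatmentSummary],
) -> str:
    """Genotype class of one compound from its qualifying treatments.

    Precedence: her1_only, then hes6_suppressed, then her1_enhanced, then
    wild_type_supported / mixed.  Suppression is tested before enhancement
    because a compound whose phenotype vanishes in hes6 is informative about
    that pathway regardless of its her1 response.
    """
    if not qualifying:
        return "wild_type_supported"
    exps = {e for _, e in qualifying}
    if exps == {"her1"}:
        return "her1_only"
    qual_set = set(qualifying)
    # hes6_suppressed: qualifying in wt and/or her1 at some concentration
    # where hes6 does not qualify.
    for conc, exp in qualifying:
        if exp in WILD_TYPE_EXPERIMENTS or exp == "her1":
            if (conc, "hes6") not in qual_set:
                return "hes6_suppressed"
    # her1_enhanced: qualifies in her1 with strictly higher seg_mean than the
    # best wild-type treatment at the same concentration.
    for conc, exp in qualifying:
        if exp != "her1":
            continue
        wt = [
            summaries[(conc, w)].seg_mean
            for w in WILD_TYPE_EXPERIMENTS
            if (conc, w) in summaries
        ]
        if wt and summaries[(conc, "her1")].seg_mean > max(wt):
            return "her1_enhanced"
    if exps & set(WILD_TYPE_EXPERIMENTS):
        return "wild_type_supported"
    return "mixed"


def call_hits(
    table: ScreenTable, config: RankingConfig = DEFAULT_RANKING_CONFIG
) -> List[HitCall]:
    """Compound-level hit calls with the wild-type reproducibility filter.

    A compound is a hit when at least one treatment satisfies the
    direct-segmentation predicate, unless all its qualifying treatments sit
    in a single wild-type replicate (none in the other replicate or in a
    mutant): such compounds are flagged as irreproducible false positives.
    """
    qualifying, summaries = _qualifying_by_compound(table, config)
    calls = []
    for compound in table.compounds:
        quals = sorted(
            qualifying[compound],
            key=lambda q: (q[0], _experiment_sort_key(q[1])),
        )
        exps = {e for _, e in quals}
        irreproducible = bool(quals) and (exps == {"wt_A"} or exps == {"wt_B"})
        is_hit = bool(quals) and not irreproducible
        concs = tuple(sorted({c for c, _ in quals}))
        summs = summaries[compound].values()
        calls.append(
            HitCall(
                compound_id=compound,
                is_hit=is_hit,
                qualifying_treatments=quals,
                excluded_as_irreproducible=irreproducible,
                genotype_class=_classify_genotype(quals, summaries[compound]),
                active_concentrations=concs,
                single_concentration=len(concs) == 1,
                best_ssmd=max((s.ssmd for s in summs), default=None),
                best_mean_diff=max((s.mean_diff for s in summs), default=None),
            )
        )
    return calls


def genotype_profile(
    hits: List[HitCall], table: ScreenTable,
    config: RankingConfig = DEFAULT_RANKING_CONFIG,
) -> Dict[str, str]:
    """Recompute the genotype class for each hit call (updating in place);
    returns {compound_id: genotype_class}."""
    _, summaries = _qualifying_by_compound(table, config)
    out = {}
    for call in hits:
        cls = _classify_genotype(
            call.qualifying_treatments, summaries.get(call.compound_id, {})
        )
        call.genotype_class = cls
        out[call.compound_id] = cls
    return out


@dataclass
class MaskingSummary:
    n_hits: int
    n_single_concentration: int
    fraction_single_concentration: float
    hits_per_concentration: Dict[float, int]


def concentration_masking(hits: List[HitCall]) -> MaskingSummary:
    """Fraction of hits active at exactly one concentration, plus the number
    of hits active at each screened concentration."""
    actual = [h for h in hits if h.is_hit]
    if not actual:
        logger.warning("concentration_masking: no hits to summarize")
        return MaskingSummary(0, 0, float("nan"), {})
    n_single = sum(1 for h in actual if h.single_concentration)
    per_conc: Dict[float, int] = {}
    for h in actual:
        for c in h.active_concentrations:
            per_conc[c] = per_conc.get(c, 0) + 1
    return MaskingSummary(
        n_hits=len(actual),
        n_single_concentration=n_single,
        fraction_single_concentration=n_single / len(actual),
        hits_per_concentration=dict(sorted(per_conc.items())),
    )
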