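"""The candidate-gene screen.

Pipeline: (optional) replicate consensus for the first factor ->
intersection of all factor peak sets into common regions -> keep regions
at elements of the required chromatin state (active promoters by
default) -> assign regions to genes within the promoter or a 100-kb
window around the promoter midpoint -> gate associations on the gene's
expression class -> deduplicate to genes -> rank by cell-type
specificity.

The expression gate couples chromatin state to transcription: a region
at an *active* element supports a gene only if that gene is medium/high
expressed in the gating cell population; *poised* pairs with low and
*repressed* with not-expressed. All filters are configurable and only
ever relax monotonically: widening the window, allowing any element
state, or widening the gate can add candidates but never remove one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .chromatin_state import (
    RegulatoryElement,
    annotate_landscape,
    consensus_peaks,
    promoter_window,
    regulatory_footprint,
)
from .expression import classify_expression, specificity_rank
from .intervals import (
    GenomicInterval,
    IntervalSet,
    distance,
    filter_overlapping,
    multi_intersect,
    overlaps,
)
from .io_formats import ExpressionTable, GeneTable

__all__ = ["ScreenConfig", "GeneAssociation", "CandidateTable", "common_regions",
           "assign_regions_to_genes", "screen", "ConfigError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Screen configuration inconsistent with the provided inputs."""


#: Default coupling of element state to allowed expression classes.
DEFAULT_EXPRESSION_GATE: dict[str, tuple[str, ...]] = {
    "active": ("medium", "high"),
    "poised": ("low",),
    "repressed": ("not",),
}


@dataclass
class ScreenConfig:
    """All tunable parameters of the screen.

    ``common_mode`` is either ``"footprint"`` (bases covered by every
    factor; the default) or ``"anchor:<label>"`` (whole peaks of the
    named factor that overlap every other factor's set).
    ``required_state`` restricts common regions to those at active
    promoter elements (``"active_promoter"``, default) or keeps all
    (``"any"``). ``gating_celltype``/``target_celltype`` name the
    expression columns used for class gating and specificity ranking;
    both default to the first column of the expression table.
    """

    factors: list[str] = field(default_factory=list)
    promoter_upstream_bp: int = 1000
    promoter_downstream_bp: int = 10
    gene_window_bp: int = 100_000
    min_overlap_bp: int = 1
    common_mode: str = "footprint"
    required_state: str = "active_promoter"
    biotype_filter: str | None = "protein_coding"
    expression_gate: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_EXPRESSION_GATE.items()}
    )
    gating_celltype: str | None = None
    target_celltype: str | None = None
    specificity_metric: str = "log_ratio_max"
    bivalent_as: str | None = None
    normalize_chrom_names: bool = False

    def __post_init__(self) -> None:
        for name in ("promoter_upstream_bp", "promoter_downstream_bp",
                     "gene_window_bp", "min_overlap_bp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.required_state not in {"active_promoter", "any"}:
            raise ConfigError(f"unknown required_state {self.required_state!r}")
        if self.common_mode != "footprint" and not self.common_mode.startswith("anchor:"):
            raise ConfigError(f"unknown common_mode {self.common_mode!r}")


@dataclass
class GeneAssociation:
    """One supporting link between a common region and a gene."""

    gene_id: str
    region: GenomicInterval
    link_kind: str  # "in_promoter" | "within_window"
    distance_bp: int
    element_state: str
    expression_class: str  # "not" | "low" | "medium" | "high" | "unknown"
    gate_passed: bool

    def __post_init__(self) -> None:
        if self.link_kind == "in_promoter" and self.distance_bp != 0:
            raise ValueError("in_promoter associations must have distance 0")


@dataclass
class CandidateTable:
    """Screen output: candidate genes plus the funnel summary.

    ``candidates`` has columns n_supporting_regions, link_kinds,
    specificity_score, rank (rank 1 = most target-specific).
    ``associations`` retains every region-gene link examined, including
    gate failures, for auditability.
    """

    candidates: pd.DataFrame
    associations: list[GeneAssociation]
    summary: dict
    common: IntervalSet = field(default_factory=IntervalSet)
    elements: list[RegulatoryElement] = field(default_factory=list)

    def candidate_ids(self) -> list[str]:
        return list(self.candidates.index)


def common_regions(
    peaks_by_factor: dict[str, IntervalSet], config: ScreenConfig
) -> IntervalSet:
    """Regions bound by every factor of the screen.

    Footprint mode returns the per-base intersection of all factor sets;
    anchor mode returns the anchor factor's peaks (kept whole) that
    overlap every other factor's set.
    """
    factors = config.factors or list(peaks_by_factor)
    if len(factors) < 2:
        raise ConfigError("common_regions needs >= 2 factors")
    missing = [f for f in factors if f not in peaks_by_factor]
    if missing:
        raise ConfigError(f"factor(s) named in config but not provided: {missing}")
    sets = [peaks_by_factor[f] for f in factors]
    if config.common_mode == "footprint":
        return multi_intersect(sets)
    anchor_label = config.common_mode.split(":", 1)[1]
    if anchor_label not in peaks_by_factor:
        raise ConfigError(f"anchor factor {anchor_label!r} not provided")
    result = peaks_by_factor[anchor_label]
    for f in factors:
        if f == anchor_label:
            continue
        result = filter_overlapping(result, peaks_by_factor[f], config.min_overlap_bp)
    return result


def assign_regions_to_genes(
    regions: IntervalSet,
    elements: list[RegulatoryElement],
    genes: GeneTable,
    expr_classes: dict[str, str],
    config: ScreenConfig,
) -> list[GeneAssociation]:
    """Link each region to every gene it can regulate.

    A region links to a gene either by overlapping its promoter window
    (``in_promoter``, distance 0) or by lying within ``gene_window_bp``
    of the promoter midpoint (``within_window``; distance measured from
    the midpoint to the nearest base of the region). A region in two
    genes' windows links to both. The element state comes from the
    gene's promoter element for promoter links, otherwise from an
    enhancer element overlapping the region (unclassified if none).
    """
    promoter_by_gene = {
        e.gene_id: e for e in elements if e.locus_kind == "promoter"
    }
    enhancers = [e for e in elements if e.locus_kind == "enhancer"]
    enhancers_by_chrom: dict[str, list[RegulatoryElement]] = {}
    for e in enhancers:
        enhancers_by_chrom.setdefault(e.interval.chrom, []).append(e)

    genes_by_chrom: dict[str, list] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    out: list[GeneAssociation] = []
    for region in regions:
        # Enhancer context of the region, used for non-promoter links:
        # the overlapping enhancer with the largest shared footprint.
        enh_state = "unclassified"
        best_ov = 0
        for e in enhancers_by_chrom.get(region.chrom, []):
            ov = min(region.end, e.interval.end) - max(region.start, e.interval.start)
            if ov >= config.min_overlap_bp and ov > best_ov:
                best_ov = ov
                enh_state = e.state
        for gene in genes_by_chrom.get(region.chrom, []):
            pelem = promoter_by_gene.get(gene.gene_id)
            window = (
                pelem.interval
                if pelem is not None
                else promoter_window(
                    gene, config.promoter_upstream_bp, config.promoter_downstream_bp
                )
            )
            if overlaps(region, window, config.min_overlap_bp):
                link_kind, dist = "in_promoter", 0
                state = pelem.state if pelem is not None else "unclassified"
            else:
                dist = distance(window.midpoint(), region)
                if dist > config.gene_window_bp:
                    continue
                link_kind = "within_window"
                state = enh_state
            expr_class = expr_classes.get(gene.gene_id)
            if expr_class is None:
                logger.warning(
                    "gene %s has no expression class; association kept with gate_passed=False",
                    gene.gene_id,
                )
                out.append(
                    GeneAssociation(gene.gene_id, region, link_kind, dist, state,
                                    "unknown", False)
                )
                continue
            allowed = config.expression_gate.get(state, ())
            out.append(
                GeneAssociation(
                    gene.gene_id, region, link_kind, dist, state,
                    expr_class, expr_class in allowed,
                )
            )
    return out


def screen(
    peaks_by_factor: dict[str, IntervalSet],
    mark_peaks: dict[str, IntervalSet],
    genes: GeneTable,
    expression: ExpressionTable,
    config: ScreenConfig,
    replicate2: IntervalSet | None = None,
) -> CandidateTable:
    """Run the full screen and return the candidate table plus summary.

    ``replicate2``, if given, is a second replicate of the *first*
    configured factor; that factor's peaks are then reduced to the
    replicate consensus (reproduced in replicate 2, or in a marked
    regulatory element) before intersection.
    """
    factors = config.factors or list(peaks_by_factor)
    missing = [f for f in factors if f not in peaks_by_factor]
    if missing:
        raise ConfigError(f"factor(s) named in config but not provided: {missing}")

    elements = annotate_landscape(
        mark_peaks,
        genes,
        upstream_bp=config.promoter_upstream_bp,
        downstream_bp=config.promoter_downstream_bp,
        min_overlap_bp=config.min_overlap_bp,
        bivalent_as=config.bivalent_as,
    )

    peaks = dict(peaks_by_factor)
    consensus_size = None
    if replicate2 is not None:
        first = factors[0]
        consensus = consensus_peaks(
            peaks[first], replicate2, regulatory_footprint(elements),
            config.min_overlap_bp,
        )
        consensus_size = len(consensus)
        logger.info("consensus for %s: %d of %d replicate-1 peaks retained",
                    first, len(consensus), len(peaks[first]))
        peaks[first] = consensus

    regions = common_regions(peaks, config)
    n_common = len(regions)

    active_promoters = IntervalSet(
        [e.interval for e in elements
         if e.locus_kind == "promoter" and e.state == "active"]
    )
    at_active = filter_overlapping(regions, active_promoters, config.min_overlap_bp)
    n_active = len(at_active)

    kept_regions = at_active if config.required_state == "active_promoter" else regions

    # Expression classes in the gating cell population.
    gating_ct = config.gating_celltype or expression.cell_types[0]
    if gating_ct not in expression.cell_types:
        raise ConfigError(f"gating_celltype {gating_ct!r} not in expression table")
    thresholds, expr_classes = classify_expression(expression.matrix[gating_ct])

    associations = assign_regions_to_genes(
        kept_regions, elements, genes, expr_classes, config
    )

    biotypes = {g.gene_id: g.biotype for g in genes}
    passed = [
        a for a in associations
        if a.gate_passed
        and (config.biotype_filter is None or biotypes.get(a.gene_id) == config.biotype_filter)
    ]
    support: dict[str, list[GeneAssociation]] = {}
    for a in passed:
        support.setdefault(a.gene_id, []).append(a)

    candidate_ids = sorted(support)
    target_ct = config.target_celltype or expression.cell_types[0]
    in_matrix = [g for g in candidate_ids if g in expression.matrix.index]
    dropped = sorted(set(candidate_ids) - set(in_matrix))
    if dropped:
        logger.warning("candidates missing from expression matrix, unranked: %s", dropped)
    if in_matrix:
        ranking = specificity_rank(
            expression.matrix, target_ct, in_matrix, metric=config.specificity_metric
        )
    else:
        ranking = pd.DataFrame(columns=["specificity_score", "rank"])
        ranking.index.name = "gene_id"

    rows = []
    for gene_id in ranking.index:
        assocs = support[gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "n_supporting_regions": len({(a.region.chrom, a.region.start, a.region.end)
                                             for a in assocs}),
                "link_kinds": ",".join(sorted({a.link_kind for a in assocs})),
                "specificity_score": float(ranking.loc[gene_id, "specificity_score"]),
                "rank": int(ranking.loc[gene_id, "rank"]),
            }
        )
    candidates = pd.DataFrame(
        rows, columns=["gene_id", "n_supporting_regions", "link_kinds",
                       "specificity_score", "rank"]
    ).set_index("gene_id")

    summary = {
        "n_sites_per_factor": {f: len(peaks[f]) for f in factors},
        "consensus_size": consensus_size,
        "n_common_regions": n_common,
        "n_active_promoter_regions": n_active,
        "pct_active_promoter": round(100.0 * n_active / n_common, 4) if n_common else 0.0,
        "n_associations": len(associations),
        "n_gate_passed_associations": len(passed),
        "n_candidate_genes": len(candidates),
        "expression_thresholds": {
            "q1": thresholds.q1, "mean": thresholds.mean, "q3": thresholds.q3,
            "gating_celltype": gating_ct,
        },
        "target_celltype": target_ct,
        "required_state": config.required_state,
        "common_mode": config.common_mode,
        "biotype_filter": config.biotype_filter,
    }
    return CandidateTable(
        candidates=candidates,
        associations=associations,
        summary=summary,
        common=regions,
        elements=elements,
    )
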