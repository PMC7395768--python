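"""Synthetic paired multi-omics cohorts with full ground-truth bookkeeping.

The generator emulates the statistical structure of an acute-UV suction
blister study: a paired control/irradiated design over ``n_subjects``
subjects, hypomethylation-biased irradiation effects on CpGs with a gradient
across CpG-island relations, differentially expressed genes of which a
fraction are DEMGs (expression change anti-correlated with the methylation
change of their promoter/enhancer CpGs), MED-predictive baseline features on
both molecular levels, and three latent molecular phototypes carrying
subtype-specific irradiation-response pathways.

Methylation is generated on the latent M scale (Gaussian) and mapped to Beta
through the logistic transform ``Beta = 2^M / (1 + 2^M)``; expression is
generated as Gaussian log2(TPM+1) and exponentiated back. Planted effects are
applied on those latent scales, which is where all downstream statistics
operate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import (
    CONTROL,
    IRRADIATED,
    ISLAND_RELATIONS,
    CpGManifest,
    GenomicBlock,
    PairedOmicsCohort,
)

# region classes a coupled CpG may carry (Intergenic links never qualify a gene)
_REGULATORY_CLASSES = ("TSS200", "TSS1500", "Exon", "Enhancer")
_REGULATORY_WEIGHTS = (0.25, 0.20, 0.15, 0.40)  # enhancers most frequent
_ALL_CLASS_WEIGHTS = {
    "TSS200": 0.15, "TSS1500": 0.10, "Exon": 0.15,
    "Enhancer": 0.20, "Intergenic": 0.40,
}
_ISLAND_PROPS = {"OpenSea": 0.45, "Shelf": 0.10, "Shore": 0.20, "Island": 0.25}

N_CHROMOSOMES = 22


@dataclass
class EffectSizes:
    """Location/scale of planted irradiation effects on latent scales."""

    log2fc_loc: float = 1.0
    log2fc_scale: float = 0.4
    log2fc_min: float = 0.6       # keeps affected genes above the DEMG cutoff
    delta_m_loc: float = 1.0
    delta_m_scale: float = 0.4
    delta_m_min: float = 0.3
    demg_delta_m_min: float = 0.45  # coupled CpGs clear the |dM|>0.2 filter
    subtype_shift: float = 2.0      # irradiated-only shift of subtype features
    med_slope_min: float = 0.8      # per unit of standardized MED
    med_slope_max: float = 1.2


@dataclass
class CohortConfig:
    """Study-design constants for one synthetic cohort.

    Defaults mirror the emulated study: 32 subjects, 65.1% of affected CpGs
    hypomethylated with a hypomethylation gradient rising from open sea to
    CpG islands, 32.4% of genes affected, and MED distributions per latent
    subtype spanning roughly 100-200 mJ/cm^2.
    """

    n_subjects: int = 32
    n_genes: int = 2000
    n_cpgs: int = 20000
    subtype_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    med_means: tuple = (100.0, 150.0, 200.0)   # mJ/cm^2 per subtype
    med_sd: float = 15.0
    frac_cpgs_affected: float = 0.25
    frac_hypo_among_affected: float = 0.651
    frac_genes_affected: float = 0.324
    frac_demg: float = 0.30
    n_med_predictive_features: int = 30        # per data level
    island_gradient: tuple = (0.57, 0.63, 0.70, 0.78)  # OpenSea<=Shelf<=Shore<=Island
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    noise_sd: float = 0.3
    subject_sd: float = 0.5
    n_subtype_signature_genes: int = 60
    n_subtype_signature_cpgs: int = 200
    n_shared_pathway_genes: int = 40
    n_null_gene_sets: int = 20
    n_blocks: int = 40
    n_concordant_blocks: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if len(props) != 3 or not np.isclose(props.sum(), 1.0) or (props < 0).any():
            raise ValueError("subtype_proportions must be a length-3 simplex vector")
        if not np.all(np.diff(self.med_means) > 0):
            raise ValueError("med_means must be strictly increasing")
        for name in ("frac_cpgs_affected", "frac_hypo_among_affected",
                     "frac_genes_affected", "frac_demg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {v})")
        grad = np.asarray(self.island_gradient, dtype=float)
        if len(grad) != 4 or (np.diff(grad) < 0).any():
            raise ValueError("island_gradient must be 4 non-decreasing fractions")
        if ((grad < 0) | (grad > 1)).any():
            raise ValueError("island_gradient fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subtype_proportions"] = list(self.subtype_proportions)
        d["med_means"] = list(self.med_means)
        d["island_gradient"] = list(self.island_gradient)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "effect_sizes" in d and isinstance(d["effect_sizes"], dict):
            d["effect_sizes"] = EffectSizes(**d["effect_sizes"])
        for key in ("subtype_proportions", "med_means", "island_gradient"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Truth ledger for recovery tests: everything the generator planted."""

    affected_cpgs: pd.Series          # cpg_id -> planted delta-M (signed)
    affected_genes: pd.Series         # gene_id -> planted log2FC (signed)
    demg_genes: set                   # genes with coupled methylation
    med_predictive: dict              # level -> Series(feature_id -> slope)
    subtype_pathways: dict            # pathway name -> set of gene ids
    subtype_gene_sign: dict           # pathway name -> Series(gene -> signed shift)
    subtype_cpgs: dict                # subtype (1..3) -> Series(cpg -> signed shift)
    shared_pathway: str
    shared_pathway_genes: set
    block_info: pd.DataFrame          # block_id, concordant, planted_mean_delta
    block_members: dict               # block_id -> list of member affected cpg ids

    def hypo_fraction_planted(self) -> float:
        return float((self.affected_cpgs < 0).mean())

    def to_json(self, path) -> None:
        payload = {
            "affected_cpgs": self.affected_cpgs.to_dict(),
            "affected_genes": self.affected_genes.to_dict(),
            "demg_genes": sorted(self.demg_genes),
            "med_predictive": {k: v.to_dict() for k, v in self.med_predictive.items()},
            "subtype_pathways": {k: sorted(v) for k, v in self.subtype_pathways.items()},
            "subtype_gene_sign": {k: v.to_dict() for k, v in self.subtype_gene_sign.items()},
            "subtype_cpgs": {str(k): v.to_dict() for k, v in self.subtype_cpgs.items()},
            "shared_pathway": self.shared_pathway,
            "shared_pathway_genes": sorted(self.shared_pathway_genes),
            "block_info": self.block_info.to_dict(orient="list"),
            "block_members": self.block_members,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# deterministic layout shared by generate_cohort and generate_annotations
# ---------------------------------------------------------------------------

def _allocate_counts(total: int, weights: np.ndarray, rng) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights` (largest remainder)."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        out = np.zeros(len(weights), dtype=int)
        out[: total] = 1
        return out
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _hypo_counts_per_relation(n_per_relation: np.ndarray, gradient: np.ndarray,
                              total_hypo: int) -> np.ndarray:
    """Per-island-relation hypomethylated counts summing to ``total_hypo``.

    Scales the gradient so the weighted mean matches the requested total,
    then repairs rounding so realized fractions stay non-decreasing
    OpenSea -> Island.
    """
    n = n_per_relation.astype(int)
    expected = float((gradient * n).sum())
    scale = total_hypo / expected if expected > 0 else 0.0
    target = np.clip(gradient * scale, 0.0, 1.0) * n
    counts = np.floor(target).astype(int)
    # distribute the remainder preferring the largest fractional parts
    rem = total_hypo - counts.sum()
    frac = target - np.floor(target)
    for idx in np.argsort(-frac):
        if rem <= 0:
            break
        if counts[idx] < n[idx]:
            counts[idx] += 1
            rem -= 1
    # any leftover (clipping) goes wherever capacity remains
    for idx in range(len(counts)):
        while rem > 0 and counts[idx] < n[idx]:
            counts[idx] += 1
            rem -= 1
    # repair monotonicity of fractions (OpenSea -> Island non-decreasing)
    for _ in range(10):
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = np.where(n > 0, counts / np.maximum(n, 1), 0.0)
        ok = True
        for i in range(len(fr) - 1):
            if n[i] and n[i + 1] and fr[i] > fr[i + 1] + 1e-12:
                ok = False
                if counts[i + 1] < n[i + 1] and counts[i] > 0:
                    counts[i] -= 1
                    counts[i + 1] += 1
        if ok:
            break
    return counts


class _CohortPlan:
    """Deterministic layout derived from the config seed.

    Both :func:`generate_cohort` and :func:`generate_annotations` build this
    plan, so matrices and annotations agree on ids, links and planted effects
    without sharing state.
    """

    def __init__(self, config: CohortConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        es = config.effect_sizes
        n_genes, n_cpgs = config.n_genes, config.n_cpgs

        self.gene_ids = np.array([f"GENE{i:05d}" for i in range(n_genes)])
        self.cpg_ids = np.array([f"cg{i:08d}" for i in range(n_cpgs)])

        # ---- genomic coordinates: CpGs split over chromosomes, positions
        # strictly increasing within each
        n_chrom = min(N_CHROMOSOMES, n_cpgs) or 1
        chrom_counts = _allocate_counts(n_cpgs, np.ones(n_chrom), rng)
        chroms, positions = [], []
        for ci, cnt in enumerate(chrom_counts):
            gaps = rng.integers(500, 5000, size=cnt)
            pos = np.cumsum(gaps)
            chroms.extend([f"chr{ci + 1}"] * cnt)
            positions.extend(pos.tolist())
        self.chromosome = np.array(chroms)
        self.position = np.array(positions, dtype=int)

        # ---- island relations
        rel_names = list(ISLAND_RELATIONS)
        rel_probs = np.array([_ISLAND_PROPS[r] for r in rel_names])
        self.island_relation = rng.choice(rel_names, size=n_cpgs, p=rel_probs)

        # ---- affected genes and DEMG subset
        n_aff_g = int(round(config.frac_genes_affected * n_genes))
        aff_gene_idx = rng.choice(n_genes, size=n_aff_g, replace=False)
        gene_sign = rng.choice([-1.0, 1.0], size=n_aff_g)
        gene_mag = np.maximum(
            es.log2fc_min,
            np.abs(rng.normal(es.log2fc_loc, es.log2fc_scale, size=n_aff_g)),
        )
        self.gene_log2fc = pd.Series(
            gene_sign * gene_mag, index=self.gene_ids[aff_gene_idx]
        )
        n_demg = int(round(config.frac_demg * n_aff_g))
        n_aff_c = int(round(config.frac_cpgs_affected * n_cpgs))
        if n_aff_c == 0:
            n_demg = 0  # no CpG effects planted, so no coupled genes either
        demg_ids = rng.choice(self.gene_log2fc.index.to_numpy(), size=n_demg,
                              replace=False) if n_demg else np.array([], dtype=object)
        self.demg_genes = set(demg_ids.tolist())

        # ---- affected CpGs; DEMG-coupled CpGs carry forced anti-signs
        aff_cpg_idx = rng.choice(n_cpgs, size=n_aff_c, replace=False)
        aff_cpg_ids = self.cpg_ids[aff_cpg_idx]

        links = []  # (cpg_id, gene_id, region_class)
        delta_m = pd.Series(np.zeros(n_aff_c), index=aff_cpg_ids)
        pool = list(aff_cpg_ids)
        rng.shuffle(pool)
        cursor = 0
        demg_cpg_ids = []
        for gene in sorted(self.demg_genes):
            k = int(rng.integers(3, 6))
            take = pool[cursor: cursor + k]
            cursor += k
            if len(take) < 3:
                raise ValueError(
                    "not enough affected CpGs to couple every DEMG gene; "
                    "increase n_cpgs or frac_cpgs_affected"
                )
            sign = -np.sign(self.gene_log2fc[gene])
            for cpg in take:
                mag = max(es.demg_delta_m_min,
                          abs(rng.normal(es.delta_m_loc, es.delta_m_scale)))
                delta_m[cpg] = sign * mag
                cls = rng.choice(_REGULATORY_CLASSES, p=_REGULATORY_WEIGHTS)
                links.append((cpg, gene, cls))
                demg_cpg_ids.append(cpg)
        self.demg_cpgs = set(demg_cpg_ids)

        # ---- remaining affected CpGs: hypo quota per island relation
        free = np.array(pool[cursor:])
        total_hypo = int(round(config.frac_hypo_among_affected * n_aff_c))
        hypo_from_demg = int((delta_m[list(self.demg_cpgs)] < 0).sum()) if self.demg_cpgs else 0
        quota = max(0, min(total_hypo - hypo_from_demg, len(free)))
        rel_of_free = pd.Series(
            self.island_relation[pd.Index(self.cpg_ids).get_indexer(free)], index=free
        ) if len(free) else pd.Series(dtype=object)
        n_per_rel = np.array([(rel_of_free == r).sum() for r in rel_names])
        grad = np.asarray(config.island_gradient, dtype=float)
        hypo_per_rel = _hypo_counts_per_relation(n_per_rel, grad, quota)
        signs = pd.Series(np.ones(len(free)), index=free)
        for r, k in zip(rel_names, hypo_per_rel):
            members = rel_of_free.index[rel_of_free == r].to_numpy()
            chosen = rng.choice(members, size=int(k), replace=False) if k else []
            signs[chosen] = -1.0
        mags = np.maximum(
            es.delta_m_min,
            np.abs(rng.normal(es.delta_m_loc, es.delta_m_scale, size=len(free))),
        )
        delta_m[free] = signs.to_numpy() * mags
        self.cpg_delta_m = delta_m

        # ---- MED-predictive features (disjoint from affected sets)
        def _pick_free(ids, used, k):
            avail = np.array(sorted(set(ids) - used))
            return rng.choice(avail, size=k, replace=False)

        used_genes = set(self.gene_log2fc.index)
        used_cpgs = set(aff_cpg_ids)
        n_med = config.n_med_predictive_features
        med_genes = _pick_free(self.gene_ids, used_genes, n_med)
        med_cpgs = _pick_free(self.cpg_ids, used_cpgs, n_med)
        slope = lambda k: (rng.choice([-1.0, 1.0], size=k)
                           * rng.uniform(es.med_slope_min, es.med_slope_max, size=k))
        self.med_predictive = {
            "expression": pd.Series(slope(n_med), index=med_genes),
            "methylation": pd.Series(slope(n_med), index=med_cpgs),
        }
        used_genes |= set(med_genes)
        used_cpgs |= set(med_cpgs)

        # ---- subtype signatures (genes shift only in their subtype's
        # irradiated samples; CpG signs hypo-biased like global effects)
        self.subtype_gene_sign = {}
        self.subtype_pathways = {}
        self.subtype_cpgs = {}
        for st in (1, 2, 3):
            name = f"SUBTYPE{st}_UV_RESPONSE"
            genes = _pick_free(self.gene_ids, used_genes,
                               config.n_subtype_signature_genes)
            used_genes |= set(genes)
            gsign = rng.choice([-1.0, 1.0], size=len(genes)) * es.subtype_shift
            self.subtype_pathways[name] = set(genes.tolist())
            self.subtype_gene_sign[name] = pd.Series(gsign, index=genes)
            cpgs = _pick_free(self.cpg_ids, used_cpgs,
                              config.n_subtype_signature_cpgs)
            used_cpgs |= set(cpgs)
            csign = np.where(
                rng.random(len(cpgs)) < config.frac_hypo_among_affected, -1.0, 1.0
            ) * es.subtype_shift
            self.subtype_cpgs[st] = pd.Series(csign, index=cpgs)

        # ---- shared UV-response pathway: upregulated affected genes
        up = self.gene_log2fc[self.gene_log2fc > 0].index.to_numpy()
        n_shared = min(config.n_shared_pathway_genes, len(up))
        self.shared_pathway = "SHARED_UV_RESPONSE"
        self.shared_pathway_genes = set(
            rng.choice(up, size=n_shared, replace=False).tolist()
        ) if n_shared else set()

        # ---- null gene sets: drawn from genes with no planted irradiation
        # response, so they are genuine negative controls for enrichment and
        # predictivity
        null_pool = np.array(sorted(
            set(self.gene_ids) - set(self.gene_log2fc.index)
            - set().union(*self.subtype_pathways.values())
        ))
        if len(null_pool) == 0:
            null_pool = self.gene_ids
        self.null_sets = {}
        for i in range(config.n_null_gene_sets):
            k = min(int(rng.integers(15, 51)), len(null_pool))
            self.null_sets[f"NULL_SET_{i:03d}"] = set(
                rng.choice(null_pool, size=k, replace=False).tolist()
            )

        # ---- remaining gene links for non-coupled CpGs
        linked = {cpg for cpg, _, _ in links}
        cls_names = list(_ALL_CLASS_WEIGHTS)
        cls_probs = np.array(list(_ALL_CLASS_WEIGHTS.values()))
        n_links = rng.choice([0, 1, 2], size=n_cpgs, p=[0.5, 0.4, 0.1])
        for i, cpg in enumerate(self.cpg_ids):
            if cpg in linked:
                continue
            for _ in range(int(n_links[i])):
                gene = self.gene_ids[int(rng.integers(0, n_genes))]
                cls = cls_names[int(rng.choice(len(cls_names), p=cls_probs))]
                links.append((cpg, gene, cls))
        self.links = pd.DataFrame(links, columns=["cpg_id", "gene_id", "region_class"])

        # ---- genomic blocks
        pos_of = pd.Series(self.position, index=self.cpg_ids)
        chrom_of = pd.Series(self.chromosome, index=self.cpg_ids)
        order = np.lexsort((self.position, self.chromosome))
        ordered_ids = self.cpg_ids[order]
        aff_set = set(aff_cpg_ids)
        other_planted = set().union(*(set(s.index) for s in self.subtype_cpgs.values()))
        other_planted |= set(med_cpgs)
        block_rows, block_members = [], {}
        n_conc = min(config.n_concordant_blocks, config.n_blocks)
        hypo_ids = delta_m[delta_m < 0].index.to_numpy()
        candidates = rng.permutation(hypo_ids) if len(hypo_ids) else []
        id_to_rank = {cid: r for r, cid in enumerate(ordered_ids)}
        used_ranks: set[int] = set()
        n_planted = 0
        # concordant blocks: contiguous windows around a planted hypomethylated
        # CpG, free of other planted signals, with a clear mean planted delta-M
        for seed_cpg in candidates:
            if n_planted >= n_conc:
                break
            r = id_to_rank[seed_cpg]
            width = int(rng.integers(8, 20))
            lo = max(0, r - width // 2)
            span = range(lo, min(lo + width, len(ordered_ids)))
            if used_ranks.intersection(span):
                continue
            window = ordered_ids[lo: lo + width]
            window = window[chrom_of[window].to_numpy() == chrom_of[seed_cpg]]
            members = [c for c in window if c in aff_set]
            if len(members) < 3 or any(c in other_planted for c in window):
                continue
            planted_mean = float(delta_m[members].mean())
            if abs(planted_mean) < 0.35:
                continue
            used_ranks.update(span)
            ref = 1.5 * planted_mean * (1.0 + 0.05 * rng.normal())
            if np.sign(ref) != np.sign(planted_mean):  # keep the planted sign
                ref = 1.5 * planted_mean
            pmin = int(pos_of[window].min()) - 1
            pmax = int(pos_of[window].max())
            bid = f"block{n_planted:03d}"
            block_rows.append((bid, str(chrom_of[seed_cpg]), pmin, pmax, ref, True,
                               planted_mean))
            block_members[bid] = members
            n_planted += 1
        for bi in range(n_planted, config.n_blocks):
            r = int(rng.integers(0, max(1, n_cpgs - 12)))
            window = ordered_ids[r: r + int(rng.integers(5, 12))]
            window = window[chrom_of[window].to_numpy() == chrom_of[window[0]]]
            members = [c for c in window if c in aff_set]
            bid = f"block{bi:03d}"
            block_rows.append((bid, str(chrom_of[window[0]]),
                               int(pos_of[window].min()) - 1,
                               int(pos_of[window].max()),
                               float(rng.normal(0.0, 0.5)), False,
                               float(delta_m[members].mean()) if members else np.nan))
            block_members[bid] = members
        self.block_table = pd.DataFrame(
            block_rows,
            columns=["block_id", "chromosome", "start", "end",
                     "reference_delta", "concordant", "planted_mean_delta"],
        )
        self.block_members = block_members


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> tuple[PairedOmicsCohort, GroundTruth]:
    """Simulate a paired cohort plus the ground truth of every planted effect.

    Deterministic given ``config.seed``: matrices, metadata and truth ledger
    are bit-identical across calls with the same config.
    """
    plan = _CohortPlan(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_sub = config.n_subjects
    subjects = np.array([f"S{i + 1:03d}" for i in range(n_sub)])

    # subtype assignment with fixed proportions (largest remainder), shuffled
    counts = _allocate_counts(n_sub, np.asarray(config.subtype_proportions), rng)
    subtype = np.repeat([1, 2, 3], counts)
    rng.shuffle(subtype)

    med = rng.normal(np.asarray(config.med_means)[subtype - 1], config.med_sd)
    med = np.maximum(med, 10.0)
    med_z = (med - med.mean()) / med.std(ddof=0)
    # Fitzpatrick: noisy discretization of MED (poor concordance is the point)
    noisy = med + rng.normal(0.0, 30.0, size=n_sub)
    edges = [112.5, 150.0, 187.5]
    fitz = 1 + np.searchsorted(edges, noisy)
    fitz = np.clip(fitz, 1, 4)

    sample_ids, sample_subject, sample_cond = [], [], []
    for s in subjects:
        for cond, tag in ((CONTROL, "ctrl"), (IRRADIATED, "irr")):
            sample_ids.append(f"{s}_{tag}")
            sample_subject.append(s)
            sample_cond.append(cond)
    sample_table = pd.DataFrame(
        {"subject": sample_subject, "condition": sample_cond},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    irr_mask = np.array([c == IRRADIATED for c in sample_cond])
    subj_idx = np.repeat(np.arange(n_sub), 2)

    def _level(ids, base_lo, base_hi, planted: pd.Series,
               med_feats: pd.Series, subtype_feats: dict, stream: int):
        r = np.random.default_rng(np.random.SeedSequence([config.seed, stream]))
        n_feat = len(ids)
        base = r.uniform(base_lo, base_hi, size=n_feat)
        subj_eff = r.normal(0.0, config.subject_sd, size=(n_feat, n_sub))
        x = base[:, None] + subj_eff[:, subj_idx]
        x += r.normal(0.0, config.noise_sd, size=(n_feat, 2 * n_sub))
        pos = pd.Index(ids)
        # irradiation effects (all subjects)
        idx = pos.get_indexer(planted.index)
        x[np.ix_(idx, np.where(irr_mask)[0])] += planted.to_numpy()[:, None]
        # MED-linear baseline (both conditions)
        idx = pos.get_indexer(med_feats.index)
        x[idx, :] += med_feats.to_numpy()[:, None] * med_z[subj_idx][None, :]
        # subtype-specific irradiated-only shifts
        for st, feats in subtype_feats.items():
            cols = np.where(irr_mask & (subtype[subj_idx] == st))[0]
            idx = pos.get_indexer(feats.index)
            x[np.ix_(idx, cols)] += feats.to_numpy()[:, None]
        return x

    subtype_genes = {
        st: plan.subtype_gene_sign[f"SUBTYPE{st}_UV_RESPONSE"] for st in (1, 2, 3)
    }
    expr_log = _level(plan.gene_ids, 2.0, 8.0, plan.gene_log2fc,
                      plan.med_predictive["expression"], subtype_genes, stream=2)
    tpm = np.maximum(np.exp2(expr_log) - 1.0, 0.0)

    meth_m = _level(plan.cpg_ids, -4.0, 4.0, plan.cpg_delta_m,
                    plan.med_predictive["methylation"], plan.subtype_cpgs, stream=3)
    beta = 1.0 / (1.0 + np.exp2(-meth_m))
    eps = 1e-9
    beta = np.clip(beta, eps, 1.0 - eps)

    cohort = PairedOmicsCohort(
        expression=pd.DataFrame(tpm, index=plan.gene_ids, columns=sample_ids),
        methylation_beta=pd.DataFrame(beta, index=plan.cpg_ids, columns=sample_ids),
        sample_table=sample_table,
        subject_table=pd.DataFrame(
            {"med": med, "fitzpatrick": fitz, "true_subtype": subtype},
            index=pd.Index(subjects, name="subject"),
        ),
    )
    truth = GroundTruth(
        affected_cpgs=plan.cpg_delta_m,
        affected_genes=plan.gene_log2fc,
        demg_genes=plan.demg_genes,
        med_predictive=plan.med_predictive,
        subtype_pathways=plan.subtype_pathways,
        subtype_gene_sign=plan.subtype_gene_sign,
        subtype_cpgs=plan.subtype_cpgs,
        shared_pathway=plan.shared_pathway,
        shared_pathway_genes=plan.shared_pathway_genes,
        block_info=plan.block_table[
            ["block_id", "concordant", "planted_mean_delta", "reference_delta"]
        ].copy(),
        block_members=plan.block_members,
    )
    return cohort, truth


def generate_annotations(config: CohortConfig):
    """Build the CpG manifest, gene-set collection and genomic-block table.

    Shares the deterministic layout of :func:`generate_cohort` for the same
    config, so planted couplings are reflected in the annotations.

    Returns
    -------
    (CpGManifest, dict[str, set[str]], list[GenomicBlock])
    """
    plan = _CohortPlan(config)
    sites = pd.DataFrame(
        {
            "chromosome": plan.chromosome,
            "position": plan.position,
            "island_relation": plan.island_relation,
        },
        index=pd.Index(plan.cpg_ids, name="cpg_id"),
    )
    manifest = CpGManifest(sites=sites, links=plan.links)

    gene_sets = {plan.shared_pathway: set(plan.shared_pathway_genes)}
    gene_sets.update({k: set(v) for k, v in plan.subtype_pathways.items()})
    gene_sets.update({k: set(v) for k, v in plan.null_sets.items()})

    blocks = [
        GenomicBlock(row.block_id, row.chromosome, int(row.start), int(row.end),
                     float(row.reference_delta))
        for row in plan.block_table.itertuples()
    ]
    return manifest, gene_sets, blocks
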