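"""Seeded synthetic-data generator with known ground truth.

The generator emulates the statistical structure of a 4-vs-4 two-group
lncRNA/mRNA microarray study on the log2 scale:

* per-feature Gaussian baselines plus Gaussian within-group noise,
* planted signed log2 group effects (the differential-expression truth),
* latent-factor co-expression modules shared across both groups, whose
  members reach |PCC| > 0.9 at the default loading/noise,
* a genomic annotation laid out so every lncRNA realizes a requested
  genomic-context class under the classifier's documented rules, with cis
  lncRNA-mRNA pairs placed at exact base-pair gaps,
* GMT gene sets sampled preferentially from the planted DE mRNAs at a
  configured odds ratio (odds 1 = null sets), and
* an RT-qPCR Ct table whose 2^-ddCt fold changes mirror the planted
  effects.

All outputs are a pure function of the seed: the same
:class:`SimulationConfig` regenerates byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from lncnet.io import AnnotationTable, ExpressionMatrix, GeneSets

# fixed spawn keys: one independent RNG stream per generator stage
_STREAM_CONFIG, _STREAM_EXPR, _STREAM_ANNOT, _STREAM_SETS, _STREAM_CT = range(5)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def mrna_id(i: int) -> str:
    return f"M{i + 1:04d}"


def lnc_id(i: int) -> str:
    return f"L{i + 1:04d}"


@dataclass
class ModuleSpec:
    """A latent-factor co-expression block.

    Each member feature gets ``loading * sign * factor`` added to its log2
    value, one factor draw per sample shared by both groups, so module
    correlation is group-independent.  ``sign`` is +1/-1 per member.
    """

    name: str
    lnc_members: list[tuple[str, int]]
    mrna_members: list[tuple[str, int]]
    loading: float = 0.95


@dataclass
class CisSpec:
    """A lncRNA placed at an exact genomic gap from a partner mRNA gene."""

    lnc: str
    mrna: str
    gap: int
    side: str = "down"  # downstream or upstream of the partner gene


@dataclass
class GeneSetSpec:
    n_enriched: int = 5
    enriched_size: int = 100
    enriched_odds: float = 10.0
    n_null: int = 20
    null_size: int = 220


@dataclass
class SimulationConfig:
    """Everything the generator needs; the seed determines all outputs."""

    seed: int = 0
    n_control: int = 4
    n_treated: int = 4
    n_mrna: int = 2000
    n_lnc: int = 3000
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.8
    noise_sd: float = 0.1
    #: optional (lo, hi): per-feature noise sd drawn uniformly, overriding
    #: the scalar; heterogeneous replicate variability is what keeps the
    #: |PCC| gate selective in the study profile
    noise_sd_range: tuple[float, float] | None = None
    planted_de: dict[str, float] = field(default_factory=dict)
    planted_modules: list[ModuleSpec] = field(default_factory=list)
    planted_classes: dict[str, int] = field(default_factory=dict)
    planted_cis: list[CisSpec] = field(default_factory=list)
    planted_antisense: list[tuple[str, str]] = field(default_factory=list)
    gene_sets: GeneSetSpec = field(default_factory=GeneSetSpec)

    # annotation layout constants (bp)
    gene_length: int = 20_000
    gene_spacing: int = 2_000_000
    chrom_count: int = 5
    origin: int = 10_000_000

    def mrna_ids(self) -> list[str]:
        return [mrna_id(i) for i in range(self.n_mrna)]

    def lnc_ids(self) -> list[str]:
        return [lnc_id(i) for i in range(self.n_lnc)]

    def validate(self) -> None:
        universe = set(self.mrna_ids()) | set(self.lnc_ids())
        unknown = set(self.planted_de) - universe
        if unknown:
            raise ValueError(f"planted DE features outside universe: {sorted(unknown)[:5]}")
        signs: dict[str, int] = {}
        for mod in self.planted_modules:
            for fid, s in mod.lnc_members + mod.mrna_members:
                if fid not in universe:
                    raise ValueError(f"module member {fid!r} outside universe")
                if s not in (-1, 1):
                    raise ValueError(f"module sign must be +-1, got {s!r}")
                if fid in signs and signs[fid] != s:
                    raise ValueError(f"module member {fid!r} has conflicting signs")
                signs[fid] = s
        for fid, eff in self.planted_de.items():
            if fid in signs and np.sign(eff) != signs[fid]:
                raise ValueError(
                    f"{fid!r}: DE effect sign conflicts with its module sign"
                )
        if any(c < 0 for c in self.planted_classes.values()):
            raise ValueError("negative class count")
        if sum(self.planted_classes.values()) > self.n_lnc:
            raise ValueError("planted class counts exceed lncRNA universe")
        if self.gene_sets.enriched_odds <= 0:
            raise ValueError("odds ratio must be positive")
        for cis in self.planted_cis:
            if cis.gap < 0:
                raise ValueError("negative cis gap")
            if cis.side not in ("down", "up"):
                raise ValueError(f"unknown cis side {cis.side!r}")


@dataclass
class GroundTruth:
    """What the generator planted, in the shapes the pipeline reports."""

    de: pd.DataFrame  # feature_id, biotype, log2_effect, direction, is_de
    module_edges: pd.DataFrame  # lncRNA, mRNA, sign
    classes: pd.DataFrame | None = None  # feature_id, lnc_class
    cis: pd.DataFrame | None = None  # lncRNA, mRNA, gap, within
    sets: pd.DataFrame | None = None  # set_name, kind, k, K, n, N, expected_p
    clean_signal: pd.DataFrame | None = None

    def de_ids(self, biotype: str, direction: str | None = None) -> list[str]:
        t = self.de[(self.de["biotype"] == biotype) & self.de["is_de"]]
        if direction is not None:
            t = t[t["direction"] == direction]
        return list(t["feature_id"])


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the log2 expression matrix.

    value = baseline + planted effect (treated samples) + sum over modules
    of loading*sign*factor + N(0, noise_sd).  The returned ground truth
    carries the planted DE table, the module edge list, and the noise-free
    signal matrix.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_EXPR)
    feature_ids = config.mrna_ids() + config.lnc_ids()
    n_feat = len(feature_ids)
    n_samp = config.n_control + config.n_treated
    sample_ids = [f"ctrl_{i+1}" for i in range(config.n_control)] + [
        f"sevo_{i+1}" for i in range(config.n_treated)
    ]
    treated = np.array([0] * config.n_control + [1] * config.n_treated, dtype=float)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_feat)
    idx = {fid: i for i, fid in enumerate(feature_ids)}

    effect = np.zeros(n_feat)
    for fid, eff in config.planted_de.items():
        effect[idx[fid]] = eff

    signal = baseline[:, None] + effect[:, None] * treated[None, :]
    for mod in config.planted_modules:
        factor = rng.standard_normal(n_samp)
        for fid, s in mod.lnc_members + mod.mrna_members:
            signal[idx[fid]] += mod.loading * s * factor

    if config.noise_sd_range is not None:
        lo, hi = config.noise_sd_range
        per_feature_sd = rng.uniform(lo, hi, size=n_feat)
    else:
        per_feature_sd = np.full(n_feat, config.noise_sd)
    noise = rng.standard_normal((n_feat, n_samp)) * per_feature_sd[:, None]
    values = pd.DataFrame(signal + noise, index=feature_ids, columns=sample_ids)
    groups = pd.Series(
        ["control"] * config.n_control + ["treated"] * config.n_treated, index=sample_ids
    )
    matrix = ExpressionMatrix(values, groups)

    de = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "biotype": ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lnc,
            "log2_effect": effect,
            "direction": np.where(effect > 0, "up", "down"),
            "is_de": effect != 0.0,
        }
    )
    edges = [
        {"lncRNA": l, "mRNA": m, "sign": "positive" if sl * sm > 0 else "negative"}
        for mod in config.planted_modules
        for l, sl in mod.lnc_members
        for m, sm in mod.mrna_members
    ]
    truth = GroundTruth(
        de=de,
        module_edges=pd.DataFrame(edges, columns=["lncRNA", "mRNA", "sign"]),
        clean_signal=pd.DataFrame(signal, index=feature_ids, columns=sample_ids),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _gene_coords(config: SimulationConfig, i: int) -> tuple[str, str, int, int]:
    chrom = f"chr{1 + i % config.chrom_count}"
    slot = i // config.chrom_count
    start = config.origin + slot * config.gene_spacing
    end = start + config.gene_length - 1
    strand = "+" if i % 2 == 0 else "-"
    return chrom, strand, start, end


def _gene_exons(start: int) -> list[tuple[int, int]]:
    return [
        (start, start + 2_999),
        (start + 8_000, start + 11_999),
        (start + 16_000, start + 19_999),
    ]


def simulate_annotation(config: SimulationConfig) -> tuple[AnnotationTable, GroundTruth]:
    """Build an annotation realizing the requested classes and cis gaps.

    Coding genes (3 exons each) are spaced 2 Mb apart across five
    chromosomes.  Class-planted lncRNAs are placed against dedicated
    non-dysregulated host genes so the only dysregulated cis relationships
    are the explicitly planted ones; pure intergenic lncRNAs live in zones
    >= 880 kb from every gene.  The returned truth holds the class of every
    lncRNA and the planted cis table (``within`` marks gaps inside 300 kb,
    for reference only; the generator places any requested gap).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_ANNOT)

    de_mrnas = {f for f in config.planted_de if f.startswith("M")}
    de_lncs = [f for f in config.lnc_ids() if config.planted_de.get(f)]

    rows: list[dict] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    gene_info: dict[str, tuple[str, str, int, int]] = {}
    for i, fid in enumerate(config.mrna_ids()):
        chrom, strand, start, end = _gene_coords(config, i)
        gene_info[fid] = (chrom, strand, start, end)
        rows.append(
            {"feature_id": fid, "symbol": fid, "biotype": "mRNA", "chrom": chrom,
             "strand": strand, "start": start, "end": end}
        )
        exons[fid] = _gene_exons(start)

    # --- decide each lncRNA's class -------------------------------------
    cis_lncs = {c.lnc for c in config.planted_cis}
    anti_hosts = dict(config.planted_antisense)  # lnc -> specific host mRNA
    class_of: dict[str, str] = {f: "intergenic" for f in config.lnc_ids()}
    for lnc in cis_lncs:
        class_of[lnc] = "intergenic"
    for lnc, _host in config.planted_antisense:
        class_of[lnc] = "natural_antisense"

    # dysregulated lncRNAs take the planted classes first (the class mix is
    # a statement about the DE set); any surplus spills onto the others
    de_part = [f for f in de_lncs if f not in cis_lncs and f not in anti_hosts]
    other = [
        f for f in config.lnc_ids()
        if f not in set(de_part) | cis_lncs | set(anti_hosts)
    ]
    pool = [de_part[i] for i in rng.permutation(len(de_part))] + [
        other[i] for i in rng.permutation(len(other))
    ]
    remaining = dict(config.planted_classes)
    # the already-forced placements consume their share of the request
    remaining["intergenic"] = max(
        0, remaining.get("intergenic", 0) - len(cis_lncs)
    )
    remaining["natural_antisense"] = max(
        0, remaining.get("natural_antisense", 0) - len(anti_hosts)
    )
    for cls in ("exon_sense_overlapping", "natural_antisense", "intronic_antisense",
                "bidirectional", "intergenic"):
        want = remaining.get(cls, 0)
        take, pool = pool[:want], pool[want:]
        for f in take:
            class_of[f] = cls

    # --- place them ------------------------------------------------------
    host_pool = iter(
        f for f in config.mrna_ids()
        if f not in de_mrnas and f not in {c.mrna for c in config.planted_cis}
    )
    zone_counter = 0
    zone_capacity = 200
    zone_index = 0

    def next_intergenic_coords() -> tuple[str, str, int, int]:
        nonlocal zone_counter, zone_index
        if zone_counter >= zone_capacity:
            zone_counter = 0
            zone_index += 1
        chrom = f"chr{1 + zone_index % config.chrom_count}"
        slot = zone_index // config.chrom_count
        base = config.origin + slot * config.gene_spacing + 900_000
        start = base + zone_counter * 1_000
        zone_counter += 1
        return chrom, "+", start, start + 799

    cis_by_lnc = {c.lnc: c for c in config.planted_cis}
    for fid in config.lnc_ids():
        cls = class_of[fid]
        if fid in cis_by_lnc:
            c = cis_by_lnc[fid]
            chrom, gstrand, gstart, gend = gene_info[c.mrna]
            if c.side == "down":
                start = gend + c.gap + 1
                end = start + 799
            else:
                end = gstart - c.gap - 1
                start = end - 799
                if start < 1:
                    raise ValueError(f"cis placement for {fid} has negative coordinates")
            strand = gstrand  # same strand: never antisense/bidirectional
        elif cls == "intergenic":
            chrom, strand, start, end = next_intergenic_coords()
        else:
            host = anti_hosts.get(fid)
            if host is None:
                host = next(host_pool, None)
                if host is None:
                    raise ValueError("ran out of host genes for class placement")
            chrom, gstrand, gstart, gend = gene_info[host]
            flip = {"+": "-", "-": "+"}
            if cls == "exon_sense_overlapping":
                strand, start, end = gstrand, gstart + 9_000, gstart + 9_999
            elif cls == "natural_antisense":
                strand, start, end = flip[gstrand], gstart + 9_000, gstart + 9_999
            elif cls == "intronic_antisense":
                strand, start, end = flip[gstrand], gstart + 3_500, gstart + 7_499
            elif cls == "bidirectional":
                if gstrand == "+":
                    strand, start, end = "-", gstart - 900, gstart - 401
                else:
                    strand, start, end = "+", gend + 401, gend + 900
            else:  # pragma: no cover - exhaustive over LNC_CLASSES
                raise ValueError(f"unknown class {cls!r}")
        rows.append(
            {"feature_id": fid, "symbol": fid, "biotype": "lncRNA", "chrom": chrom,
             "strand": strand, "start": start, "end": end}
        )

    annotation = AnnotationTable(pd.DataFrame(rows), exons)
    classes = pd.DataFrame(
        {"feature_id": config.lnc_ids(),
         "lnc_class": [class_of[f] for f in config.lnc_ids()]}
    )
    cis = pd.DataFrame(
        [
            {"lncRNA": c.lnc, "mRNA": c.mrna, "gap": c.gap, "within": c.gap <= 300_000}
            for c in config.planted_cis
        ],
        columns=["lncRNA", "mRNA", "gap", "within"],
    )
    truth = GroundTruth(
        de=pd.DataFrame(columns=["feature_id", "biotype", "log2_effect", "direction", "is_de"]),
        module_edges=pd.DataFrame(columns=["lncRNA", "mRNA", "sign"]),
        classes=classes,
        cis=cis,
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def simulate_gene_sets(
    config: SimulationConfig, n_null: int | None = None
) -> tuple[GeneSets, pd.DataFrame]:
    """Build GMT gene sets with known expected Fisher p per set.

    Enriched sets sample members from the mRNA background preferentially
    from the planted DE mRNAs at ``enriched_odds`` (weighted sampling
    without replacement); null sets are uniform draws (odds 1).  The truth
    table records each set's realized overlap with the DE list and the
    exact one-sided hypergeometric p that overlap implies.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_SETS)
    spec = config.gene_sets
    if max(spec.enriched_size, spec.null_size) > config.n_mrna:
        raise ValueError("gene-set size exceeds the mRNA background")
    background = np.array(config.mrna_ids())
    N = len(background)
    de = np.array([f in config.planted_de for f in background])
    n_de = int(de.sum())

    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    records = []

    def add_set(name, kind, members):
        members = sorted(members)
        k = int(de[np.isin(background, members)].sum())
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n_de))
        sets[name] = members
        desc[name] = kind
        records.append(
            {"set_name": name, "kind": kind, "k": k, "K": K, "n": n_de, "N": N,
             "expected_p": min(p, 1.0)}
        )

    for j in range(spec.n_enriched):
        # Gumbel-top-k trick == weighted sampling without replacement
        w = np.where(de, spec.enriched_odds, 1.0)
        keys = np.log(w) + rng.gumbel(size=N)
        members = background[np.argsort(-keys)[: spec.enriched_size]]
        add_set(f"enriched_{j+1:03d}", "enriched", members)

    count_null = spec.n_null if n_null is None else n_null
    for j in range(count_null):
        members = rng.choice(background, size=spec.null_size, replace=False)
        add_set(f"null_{j+1:04d}", "null", members)

    truth = pd.DataFrame(records)
    return GeneSets(sets, desc), truth


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(config: SimulationConfig, n_genes: int = 8,
                      ct_noise_sd: float = 0.25) -> pd.DataFrame:
    """RT-qPCR Ct table for a few planted DE features.

    Treated samples shift their dCt by minus the planted log2 effect, so
    2^-ddCt recovers the planted fold change on average.  Picks up to
    ``n_genes`` DE features (lncRNAs and mRNAs alternating).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_CT)
    de_l = [f for f in config.lnc_ids() if config.planted_de.get(f)]
    de_m = [f for f in config.mrna_ids() if config.planted_de.get(f)]
    genes = []
    for a, b in zip(de_l, de_m):
        genes += [a, b]
        if len(genes) >= n_genes:
            break
    genes = genes[:n_genes]
    if not genes:
        raise ValueError("no planted DE features to assay")

    rows = []
    samples = [("control", f"ctrl_{i+1}") for i in range(config.n_control)] + [
        ("treated", f"sevo_{i+1}") for i in range(config.n_treated)
    ]
    for gene in genes:
        base_dct = rng.normal(5.0, 0.5)
        effect = config.planted_de[gene]
        for group, sid in samples:
            ref = rng.normal(17.0, 0.3)
            dct = base_dct + rng.normal(0.0, ct_noise_sd)
            if group == "treated":
                dct -= effect  # one cycle earlier per log2 unit up
            rows.append(
                {"sample_id": sid, "group": group, "gene": gene,
                 "target_ct": ref + dct, "reference_ct": ref}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-study bundles
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    matrix: ExpressionMatrix
    annotation: AnnotationTable
    gene_sets: GeneSets
    ct_table: pd.DataFrame
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full coherent bundle: matrix, annotation, sets, Ct, truth."""
    matrix, truth = simulate_expression(config)
    annotation, annot_truth = simulate_annotation(config)
    gene_sets, set_truth = simulate_gene_sets(config)
    ct = simulate_ct_table(config)
    truth.classes = annot_truth.classes
    truth.cis = annot_truth.cis
    truth.sets = set_truth
    return SyntheticStudy(config, matrix, annotation, gene_sets, ct, truth)


def _split(rng: np.random.Generator, ids: list[str], *sizes: int) -> list[list[str]]:
    order = [ids[i] for i in rng.permutation(len(ids))]
    out, at = [], 0
    for s in sizes:
        out.append(order[at: at + s])
        at += s
    return out


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default desk-scale study profile.

    Emulates the structure of a neonatal 4-vs-4 sevoflurane-type microarray
    study on a 2,000 mRNA + 3,000 lncRNA universe: 148 dysregulated mRNAs
    (77 up / 71 down) and 301 dysregulated lncRNAs (234 up / 67 down);
    genomic-context mix 51.9 / 21.1 / 9.6 / 9.3 / 8.1 % (intergenic, exon
    sense-overlapping, natural antisense, intronic antisense,
    bidirectional) over the dysregulated lncRNAs; six cis pairs within
    300 kb plus four decoys beyond; no dysregulated natural-antisense
    pairs; three latent-factor co-expression modules at loading 0.95.

    Within-group noise for this profile is heteroscedastic: each feature's
    replicate sd is drawn from U(0.15, 0.8) log2 units, the spread typical
    of biological replicates on arrays.  That heterogeneity is what keeps
    the volcano filter and the |PCC| > 0.9 gate genuinely selective
    rather than saturated.  ``overrides`` replace top-level
    :class:`SimulationConfig` fields (e.g. ``noise_sd``).
    """
    overrides = {"noise_sd_range": (0.15, 0.8), **overrides}
    cfg = SimulationConfig(seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    rng = _rng(seed, _STREAM_CONFIG)

    # ---- mRNA side: 45 module members, 5 cis partners, 4 decoy partners,
    # ---- 94 free DE mRNAs; totals 77 up / 71 down
    mrna_de_ids = sorted(rng.choice(cfg.mrna_ids(), size=148, replace=False))
    mod_m, cis_m, decoy_m, free_m = _split(rng, mrna_de_ids, 45, 5, 4, 94)
    # ---- lncRNA side: 15 module members, 6 cis, 4 decoys, 276 free;
    # ---- totals 234 up / 67 down
    lnc_de_ids = sorted(rng.choice(cfg.lnc_ids(), size=301, replace=False))
    mod_l, cis_l, decoy_l, free_l = _split(rng, lnc_de_ids, 15, 6, 4, 276)

    mod_m_signs = [1] * 15 + [1] * 10 + [-1] * 5 + [1] * 12 + [-1] * 3
    mod_l_signs = [1] * 5 + [1, 1, 1, -1, -1] + [1, 1, 1, 1, -1]
    modules = []
    for j in range(3):
        modules.append(
            ModuleSpec(
                name=f"module_{j+1}",
                lnc_members=list(zip(mod_l[j * 5: (j + 1) * 5],
                                     mod_l_signs[j * 5: (j + 1) * 5])),
                mrna_members=list(zip(mod_m[j * 15: (j + 1) * 15],
                                      mod_m_signs[j * 15: (j + 1) * 15])),
                loading=0.95,
            )
        )

    def effects(ids, signs, lo=1.15, hi=2.8):
        mags = rng.uniform(lo, hi, size=len(ids))
        return {f: s * m for f, s, m in zip(ids, signs, mags)}

    planted: dict[str, float] = {}
    # module members are the network hubs: strongly dysregulated, so they
    # survive the volcano filter despite carrying the factor variance
    planted.update(effects(mod_m, mod_m_signs, lo=2.0))
    planted.update(effects(mod_l, mod_l_signs, lo=2.0))

    # cis pairs shaped like the published table: five up / one down lncRNA,
    # partners two down / three up mRNAs, one mRNA shared by two lncRNAs
    cis_lnc_eff = [1.26, 1.26, 2.70, 1.55, 1.20, -1.55]
    cis_m_eff = [-1.07, -1.20, 1.32, 1.14, 1.77]  # shared partner gets one entry
    partner_of = [0, 1, 1, 2, 3, 4]  # lnc j pairs cis_m[partner_of[j]]
    gaps = [5_000, 50_000, 120_000, 200_000, 280_000, 300_000]
    sides = ["down", "down", "up", "down", "up", "down"]
    planted.update({f: e for f, e in zip(cis_l, cis_lnc_eff)})
    planted.update({f: e for f, e in zip(cis_m, cis_m_eff)})
    planted_cis = [
        CisSpec(lnc=cis_l[j], mrna=cis_m[partner_of[j]], gap=gaps[j], side=sides[j])
        for j in range(6)
    ]
    decoy_gaps = [300_001, 350_000, 500_000, 800_000]
    planted.update(effects(decoy_l, [1, 1, -1, -1]))
    planted.update(effects(decoy_m, [1, -1, 1, -1]))
    planted_cis += [
        CisSpec(lnc=l, mrna=m, gap=g, side="down")
        for l, m, g in zip(decoy_l, decoy_m, decoy_gaps)
    ]

    # balance the free features to reach the headline up/down totals
    up_m = 37 + 3 + 2  # modules + cis partners + decoys
    down_m = 8 + 2 + 2
    free_m_signs = [1] * (77 - up_m) + [-1] * (71 - down_m)
    up_l = 12 + 5 + 2
    down_l = 3 + 1 + 2
    free_l_signs = [1] * (234 - up_l) + [-1] * (67 - down_l)
    planted.update(effects(free_m, free_m_signs))
    planted.update(effects(free_l, free_l_signs))

    cfg.planted_de = planted
    cfg.planted_modules = modules
    cfg.planted_cis = planted_cis
    # class mix over the 301 dysregulated lncRNAs (largest-remainder
    # apportionment of 51.9/21.1/9.6/9.3/8.1 %); the 10 cis/decoy lncRNAs
    # are intergenic by construction and count toward that class
    cfg.planted_classes = {
        "intergenic": 156,
        "exon_sense_overlapping": 64,
        "natural_antisense": 29,
        "intronic_antisense": 28,
        "bidirectional": 24,
    }
    cfg.validate()
    return cfg


def cnc_module_config(
    seed: int = 0,
    n_module_lnc: int = 5,
    n_module_mrna: int = 20,
    n_distractor_lnc: int = 30,
    n_distractor_mrna: int = 50,
    loading: float = 0.95,
    noise_sd: float = 0.1,
    sign_pattern: tuple[int, ...] | None = None,
) -> SimulationConfig:
    """A matrix built for testing CNC edge recovery in isolation.

    One latent-factor module drives the first ``n_module_lnc`` lncRNAs and
    ``n_module_mrna`` mRNAs; the remaining features are distractors, each
    driven by its own private unit-loading factor so every candidate has
    variance but no cross-correlation is planted.  No group effects, so
    recovery is purely a property of the correlation stage.
    """
    n_lnc = n_module_lnc + n_distractor_lnc
    n_mrna = n_module_mrna + n_distractor_mrna
    cfg = SimulationConfig(seed=seed, n_mrna=n_mrna, n_lnc=n_lnc, noise_sd=noise_sd)
    signs = list(sign_pattern) if sign_pattern else [1] * (n_module_lnc + n_module_mrna)
    lnc_members = [(lnc_id(i), signs[i]) for i in range(n_module_lnc)]
    mrna_members = [
        (mrna_id(i), signs[n_module_lnc + i]) for i in range(n_module_mrna)
    ]
    modules = [ModuleSpec("planted", lnc_members, mrna_members, loading=loading)]
    for i in range(n_module_lnc, n_lnc):
        modules.append(ModuleSpec(f"priv_l{i}", [(lnc_id(i), 1)], [], loading=1.0))
    for i in range(n_module_mrna, n_mrna):
        modules.append(ModuleSpec(f"priv_m{i}", [], [(mrna_id(i), 1)], loading=1.0))
    cfg.planted_modules = modules
    cfg.validate()
    return cfg
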