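"""Synthetic-data generators with the statistical structure each screen
assumes, so every analysis stage is testable without external downloads.

Each generator is fully determined by ``SimulationConfig.seed`` and returns
ground-truth labels alongside the data:

* :func:`simulate_tree_and_traits` -- a pure-birth (Yule) ultrametric tree
  and bivariate tip traits drawn from a multivariate normal whose
  phylogenetic covariance is the Pagel-transformed tree VCV and whose trait
  covariance encodes ``trait_correlation``.
* :func:`simulate_gene_tree_set` -- per-gene trees cloned from a species tree
  with lognormal gene-rate multipliers; a fraction of genes additionally have
  their focal terminal branch inflated (the planted "rapidly evolving" set).
* :func:`simulate_expression_study` -- negative-binomial count matrices over
  a two-tissue, replicated design with a subset of tissue-restricted
  spike-in genes, plus FPKM-like values derived with simulated gene lengths.
* :func:`simulate_contaminated_assembly` -- random contigs with planted
  contaminant hit patterns clearly above the 40% matched-unit rule and clean
  contigs clearly below it.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .io import FastaRecord, HitRecord, ValidationError
from .phylocorr import tree_vcv, lambda_cov
from .rank_screen import GeneTreeRecord, extract_branch_lengths
from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "simulate_tree_and_traits",
    "simulate_gene_tree_set",
    "simulate_expression_study",
    "simulate_contaminated_assembly",
]


@dataclass
class SimulationConfig:
    """Parameters shared by all generators; ``seed`` fully determines every
    output.

    Tree/trait parameters: ``n_tips`` (default 13, a small multi-species
    comparative panel), ``lambda_true`` in [0, 1], ``trait_correlation`` in
    [-1, 1].

    Gene-tree parameters: ``n_genes`` trees with lognormal(0, ``rate_sigma``)
    per-gene rate multipliers; an ``inflated_fraction`` of genes have the
    terminal branch of ``focal_taxon`` multiplied by
    ``focal_inflation_factor`` (> 1).

    Expression parameters: negative-binomial counts with mean scale
    ``nb_mean`` and dispersion ``nb_dispersion``; per-gene baseline
    expression is lognormal with sd ``gene_mean_sigma`` (0 gives identical
    means); a ``spike_fraction`` of genes are tissue-restricted with
    ``spike_fold`` higher mean in ``spike_group``; groups x replicates come
    from ``groups`` and ``n_replicates``.

    Assembly parameters: ``n_contigs`` contigs with lengths uniform over
    ``contig_length_range`` bp; a ``contaminant_fraction`` of contigs get
    matched-unit fractions well above 40%, the rest well below.
    """

    seed: int = 0
    # tree + traits
    n_tips: int = 13
    lambda_true: float = 1.0
    trait_correlation: float = 0.8
    # gene trees
    n_genes: int = 500
    focal_taxon: str = "T1"
    focal_inflation_factor: float = 5.0
    inflated_fraction: float = 0.1
    rate_sigma: float = 0.5
    # expression
    nb_mean: float = 50.0
    nb_dispersion: float = 0.1
    gene_mean_sigma: float = 1.0
    spike_fraction: float = 0.02
    spike_fold: float = 50.0
    spike_base_sigma: float = 0.5
    groups: tuple = ("venom_gland", "carcass")
    spike_group: str = "venom_gland"
    n_replicates: int = 3
    gene_length_range: tuple = (300, 10000)
    # assembly
    n_contigs: int = 40
    contaminant_fraction: float = 0.1
    contig_length_range: tuple = (2000, 200000)
    unit_size: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.lambda_true <= 1:
            raise ValidationError("lambda_true must be in [0, 1]")
        if not -1 <= self.trait_correlation <= 1:
            raise ValidationError("trait_correlation must be in [-1, 1]")
        if not self.focal_inflation_factor > 1:
            raise ValidationError("focal_inflation_factor must be > 1")
        for name in ("inflated_fraction", "spike_fraction", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValidationError(f"{name} must be in [0, 1)")
        if not self.nb_mean > 0:
            raise ValidationError("nb_mean must be > 0")
        if not self.nb_dispersion > 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.gene_mean_sigma < 0:
            raise ValidationError("gene_mean_sigma must be >= 0")
        if not self.spike_fold > 1:
            raise ValidationError("spike_fold must be > 1")
        if len(self.groups) < 2 or self.n_replicates < 2:
            raise ValidationError("need >= 2 groups and >= 2 replicates per group")
        if self.n_contigs < 1:
            raise ValidationError("n_contigs must be >= 1")
        if self.n_tips < 3:
            raise ValidationError("n_tips must be >= 3")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _py_rng(config: SimulationConfig, salt: int) -> random.Random:
    state = np.random.SeedSequence([config.seed, salt]).generate_state(1)[0]
    return random.Random(int(state))


def simulate_yule_tree(config: SimulationConfig) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, labelled T1..Tn.

    Standard constant-rate simulation from a crown root: with k extant
    lineages the next speciation waits Exp(k); a final Exp(n) hanging time
    after the last split keeps every terminal branch strictly positive (so
    the Brownian tip covariance stays non-singular).  The tree is ultrametric
    and rescaled to unit root-to-tip depth.
    """
    rng = _rng(config, 1)
    n = config.n_tips
    taxa = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.edge.length = 0.0
    t = 0.0
    open_lineages = [(root.new_child(), 0.0), (root.new_child(), 0.0)]
    while len(open_lineages) < n:
        k = len(open_lineages)
        t += rng.exponential(1.0 / k)
        node, birth = open_lineages.pop(int(rng.integers(0, k)))
        node.edge.length = t - birth
        open_lineages.append((node.new_child(), t))
        open_lineages.append((node.new_child(), t))
    t += rng.exponential(1.0 / n)  # hanging time: terminal branches > 0
    for node, birth in open_lineages:
        node.edge.length = t - birth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa[i]
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length /= t
    return tree


def simulate_tree_and_traits(
    config: SimulationConfig,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Yule tree plus bivariate tip traits.

    Traits are zero-mean multivariate normal with phylogenetic covariance
    C(lambda_true) and cross-trait correlation ``trait_correlation``:
    x = L u and y = rho x + sqrt(1 - rho^2) L z with L the Cholesky factor of
    C(lambda_true) and u, z independent standard normal vectors, so
    rho = +/-1 makes y an exact affine function of x.
    """
    tree = simulate_yule_tree(config)
    C, labels = tree_vcv(tree)
    S = lambda_cov(C, config.lambda_true)
    L = np.linalg.cholesky(S)
    rng = _rng(config, 2)
    u = rng.standard_normal(len(labels))
    z = rng.standard_normal(len(labels))
    rho = config.trait_correlation
    x = L @ u
    y = rho * x + math.sqrt(max(0.0, 1.0 - rho**2)) * (L @ z)
    traits = pd.DataFrame({"species": labels, "x": x, "y": y})
    return tree, traits


def simulate_gene_tree_set(
    config: SimulationConfig, species_tree: dendropy.Tree
) -> tuple[list[GeneTreeRecord], pd.DataFrame]:
    """Per-gene trees cloned from ``species_tree`` with lognormal rate
    multipliers; a random ``inflated_fraction`` of genes additionally have
    the focal terminal branch multiplied by ``focal_inflation_factor``.

    Returns the gene records (with extracted focal/total lengths) and a truth
    table (gene_id, inflated).
    """
    tips = {leaf.taxon.label for leaf in species_tree.leaf_node_iter()}
    if config.focal_taxon not in tips:
        raise ValidationError(
            f"focal taxon {config.focal_taxon!r} is not a tip of the species tree"
        )
    rng = _rng(config, 3)
    n = config.n_genes
    n_inflated = int(round(config.inflated_fraction * n))
    inflated_idx = set(rng.choice(n, size=n_inflated, replace=False).tolist())
    rates = np.exp(rng.normal(0.0, config.rate_sigma, size=n))

    records: list[GeneTreeRecord] = []
    truth = []
    width = max(4, len(str(n)))
    for i in range(n):
        gene_id = f"g{i + 1:0{width}d}"
        gtree = species_tree.clone(depth=1)
        for edge in gtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= rates[i]
        inflated = i in inflated_idx
        if inflated:
            for leaf in gtree.leaf_node_iter():
                if leaf.taxon.label == config.focal_taxon:
                    leaf.edge.length = (leaf.edge.length or 0.0) * (
                        config.focal_inflation_factor
                    )
                    break
        focal, total = extract_branch_lengths(gtree, config.focal_taxon)
        records.append(
            GeneTreeRecord(
                gene_id=gene_id,
                focal_terminal_length=focal,
                total_length=total,
                tree=gtree,
            )
        )
        truth.append({"gene_id": gene_id, "inflated": inflated})
    return records, pd.DataFrame(truth)


def simulate_expression_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """NB count and FPKM-like matrices over a replicated multi-group design.

    Per-gene baseline expression e_g is lognormal (sd ``gene_mean_sigma``);
    expected counts are proportional to gene length times expression (so the
    FPKM-like values reflect expression with length cancelled), scaled by
    ``nb_mean`` and a per-sample library factor uniform in [0.7, 1.3].
    Spiked genes have ``spike_fold`` higher expected expression in
    ``spike_group`` only (tissue-restricted).  Counts are gamma-Poisson with
    dispersion ``nb_dispersion``.

    Returns (counts, FPKM-like, truth) where truth has gene_id and spiked.
    """
    rng = _rng(config, 4)
    G = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=G).astype(float)
    ref_len = (lo + hi) / 2.0
    expr = np.exp(rng.normal(0.0, config.gene_mean_sigma, size=G))
    n_spiked = int(round(config.spike_fraction * G))
    spiked_idx = rng.choice(G, size=n_spiked, replace=False) if n_spiked else np.array([], dtype=int)
    spiked = np.zeros(G, dtype=bool)
    spiked[spiked_idx] = True
    # Tissue-restricted genes are, by definition, lowly expressed outside the
    # focal tissue: their off-tissue baseline sits near the median expression
    # scale with moderate spread, rather than spanning the genome-wide
    # dynamic range (a top off-tissue expresser is not tissue-restricted).
    if n_spiked:
        expr[spiked_idx] = np.exp(
            rng.normal(0.0, config.spike_base_sigma, size=n_spiked)
        )

    design_rows = []
    for group in config.groups:
        for rep in range(1, config.n_replicates + 1):
            design_rows.append(
                {"sample_id": f"{group}_{rep}", "group": group, "replicate": rep}
            )
    design = pd.DataFrame(design_rows)
    lib = rng.uniform(0.7, 1.3, size=len(design))

    base = config.nb_mean * expr * (lengths / ref_len)
    counts = np.empty((G, len(design)), dtype=np.int64)
    alpha = config.nb_dispersion
    for j, row in design.iterrows():
        mu = base * lib[j]
        if row["group"] == config.spike_group:
            mu = np.where(spiked, mu * config.spike_fold, mu)
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        counts[:, j] = rng.poisson(lam)

    gene_ids = [f"g{i + 1:05d}" for i in range(G)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design["sample_id"])
    col_tot = counts_df.sum(axis=0).to_numpy(dtype=float)
    col_tot[col_tot == 0] = 1.0
    fpkm = counts / (lengths[:, None] * col_tot[None, :]) * 1e9
    fpkm_df = pd.DataFrame(fpkm, index=gene_ids, columns=design["sample_id"])

    truth = pd.DataFrame(
        {"gene_id": gene_ids, "spiked": spiked, "gene_length": lengths.astype(int)}
    )
    return (
        ExpressionMatrix(counts_df, design, unit="counts"),
        ExpressionMatrix(fpkm_df, design, unit="FPKM"),
        truth,
    )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_contaminated_assembly(
    config: SimulationConfig,
) -> tuple[list[FastaRecord], list[HitRecord], pd.DataFrame]:
    """Random contigs with planted contaminant hit patterns.

    Contaminant contigs receive qualifying hits on a fraction of their
    1000-bp units drawn uniformly from [0.55, 0.95] (forced strictly above
    the 40% rule); clean contigs from [0, 0.30].  A few decoy hits with
    e-values above the cutoff are added and must not count as matches.

    Returns (contigs, hits, truth) with truth columns contig_id and
    contaminant.
    """
    rng = _rng(config, 5)
    n = config.n_contigs
    lo, hi = config.contig_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    n_cont = int(round(config.contaminant_fraction * n))
    if config.contaminant_fraction > 0:
        n_cont = max(n_cont, 1)
    cont_idx = rng.choice(n, size=n_cont, replace=False) if n_cont else np.array([], dtype=int)
    is_cont = np.zeros(n, dtype=bool)
    is_cont[cont_idx] = True

    contigs: list[FastaRecord] = []
    hits: list[HitRecord] = []
    truth = []
    for i in range(n):
        cid = f"ctg{i + 1:04d}"
        seq = _BASES[rng.integers(0, 4, size=int(lengths[i]))].tobytes().decode()
        contigs.append(FastaRecord(cid, cid, seq))
        n_units = math.ceil(lengths[i] / config.unit_size)
        if is_cont[i]:
            target = rng.uniform(0.55, 0.95)
            n_matched = max(
                int(round(target * n_units)),
                int(math.floor(0.4 * n_units)) + 1,
            )
            n_matched = min(n_matched, n_units)
        else:
            target = rng.uniform(0.0, 0.30)
            n_matched = min(
                int(round(target * n_units)), int(math.floor(0.4 * n_units))
            )
        matched_units = rng.choice(n_units, size=n_matched, replace=False)
        for k in matched_units:
            unit_len = min(config.unit_size, int(lengths[i]) - int(k) * config.unit_size)
            aln = int(rng.integers(max(1, unit_len // 2), unit_len + 1))
            hits.append(
                HitRecord(
                    query_id=f"{cid}_u{int(k) + 1}",
                    subject_id=f"bact{int(rng.integers(1, 500)):03d}",
                    percent_identity=float(np.round(rng.uniform(80, 99.9), 2)),
                    alignment_length=aln,
                    mismatches=int(rng.integers(0, max(1, aln // 10))),
                    gap_opens=int(rng.integers(0, 3)),
                    q_start=1,
                    q_end=aln,
                    s_start=1,
                    s_end=aln,
                    evalue=float(10.0 ** rng.uniform(-50, -10)),
                    bit_score=float(np.round(rng.uniform(100, 2000), 1)),
                )
            )
        # decoy hits above the e-value cutoff: never count as matches
        if n_units > 1 and rng.uniform() < 0.5:
            k = int(rng.integers(0, n_units))
            unit_len = min(config.unit_size, int(lengths[i]) - k * config.unit_size)
            hits.append(
                HitRecord(
                    query_id=f"{cid}_u{k + 1}",
                    subject_id="bact_weak",
                    percent_identity=70.0,
                    alignment_length=min(40, unit_len),
                    mismatches=10,
                    gap_opens=1,
                    q_start=1,
                    q_end=min(40, unit_len),
                    s_start=1,
                    s_end=min(40, unit_len),
                    evalue=float(10.0 ** rng.uniform(-4, -2)),
                    bit_score=40.0,
                )
            )
        truth.append({"contig_id": cid, "contaminant": bool(is_cont[i])})
    return contigs, hits, pd.DataFrame(truth)
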