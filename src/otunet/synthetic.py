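"""Synthetic OTU tables with known ground truth.

Real gut-microbiome co-occurrence studies start from 16S amplicon counts:
a few hundred OTUs after prevalence filtering, roughly a dozen samples per
group, compositional counts with excess zeros, and correlation structure
organised in modules with a mostly-positive sign pattern.  This generator
emulates those features with a latent one-factor-per-module Gaussian
model: OTU ``i`` in module ``b`` has log-abundance

    z_i = s_i * a_i * f_b + sqrt(1 - a_i^2) * eps_i

with module factor ``f_b ~ N(0,1)``, idiosyncratic noise ``eps_i``,
loading ``a_i`` and sign ``s_i in {+1, -1}``.  Within a module the planted
correlation between two OTUs is ``s_i s_j a_i a_j`` — positive pairs
co-occur, mixed-sign pairs exclude each other — and between modules it is
zero.  Ordinary members get loadings on a gradient
``a_i = sqrt(rho) * u_i`` with ``u_i`` spanning ``loading_range``, so most
pairwise correlations sit below the detection threshold and the resulting
networks are sparse, as empirical microbial networks are.  Planted hubs
carry the module factor itself (loading 1) and a high baseline abundance,
which makes them the best-connected, well-sampled taxa — the
high-connectivity keystones the pipeline should find.  Latents are
exponentiated to log-normal abundances, closed to compositions, counts
drawn multinomially at the target sequencing depth, and zeros injected by
Bernoulli masking.  Taxonomy is assigned so each module is dominated by
one phylum, which makes module-composition summaries testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu_table import RANKS, UNCLASSIFIED, OtuTable

_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Proteobacteria",
    "Actinobacteria",
    "Verrucomicrobia",
    "Fusobacteria",
    "Tenericutes",
    "Cyanobacteria",
)


@dataclass
class CommunitySpec:
    """Parameters of one synthetic community.

    Defaults mirror a typical 16S gut study arm: 200 module OTUs in 4
    correlation modules plus 100 background taxa, 12 samples, ~100k reads
    per sample, 1% injected dropout, 20% negative associations, one
    planted hub per module.
    """

    n_otus: int = 200
    n_samples: int = 12
    n_modules: int = 4
    rho: float = 0.8              # within-module latent correlation (at u = 1)
    negative_fraction: float = 0.2  # fraction of within-module pairs negative
    hubs_per_module: int = 1
    hub_loading: float = 1.0      # hub factor loading (hub = module factor)
    loading_range: tuple[float, float] = (0.55, 0.9)  # member u_i gradient
    depth: int = 100_000          # mean reads per sample
    zero_inflation: float = 0.01  # post-sampling Bernoulli zero probability
    overdispersion: float = 0.0   # log-normal depth jitter (sd of log depth)
    base_abundance_sd: float = 1.0  # spread of OTU mean log-abundances
    base_abundance_floor: float = -0.5  # min mean log-abundance of module taxa
    hub_min_abundance: float = 1.0  # floor on hub mean log-abundance
    n_background: int = 100       # unstructured taxa outside the modules
    background_share: float = 0.65  # expected fraction of reads they carry
    background_sd: float = 0.3    # latent sd of the stable background core
    background_base_sd: float = 1.2  # abundance spread of background taxa
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if not 0 <= self.negative_fraction < 0.5:
            raise ValueError(
                "negative_fraction must be in [0, 0.5) (sign-flip model)"
            )
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_modules > self.n_otus:
            raise ValueError("more modules than OTUs")
        lo, hi = self.loading_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("loading_range must satisfy 0 < lo <= hi <= 1")
        if not 0 < self.hub_loading <= 1:
            raise ValueError("hub_loading must be in (0, 1]")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted: module labels, hubs, and the pairwise sign matrix."""

    module_of: dict[str, int]
    hubs: list[str]
    sign_matrix: pd.DataFrame  # +1 / -1 within modules, 0 between
    loadings: pd.Series
    latents: pd.DataFrame = field(repr=False, default=None)  # signed latent z
    spec: CommunitySpec = field(repr=False, default=None)

    def planted_correlation(self) -> pd.DataFrame:
        """Planted latent correlation matrix: s_i s_j a_i a_j within
        modules (via signed loadings), identity diagonal, 0 elsewhere."""
        v = self.loadings.values
        r = np.outer(v, v) * (self.sign_matrix.values != 0)
        np.fill_diagonal(r, 1.0)
        return pd.DataFrame(
            r, index=self.loadings.index, columns=self.loadings.index
        )

    def planted_positive_fraction(self) -> float:
        """Fraction of planted within-module associations that are positive."""
        s = self.sign_matrix.values
        iu = np.triu_indices(s.shape[0], k=1)
        vals = s[iu]
        vals = vals[vals != 0]
        return float((vals > 0).mean())


def _module_sizes(n_otus: int, n_modules: int) -> list[int]:
    base = n_otus // n_modules
    sizes = [base] * n_modules
    for i in range(n_otus - base * n_modules):
        sizes[i] += 1
    return sizes


def _negative_count(size: int, f_neg: float) -> int:
    # pick q so that flipping round(q*size) signs yields ~f_neg mixed pairs:
    # mixed-pair fraction of a module with q flipped is 2q(1-q)
    if f_neg == 0:
        return 0
    q = (1.0 - np.sqrt(1.0 - 2.0 * f_neg)) / 2.0
    return int(round(q * size))


def generate_community(spec: CommunitySpec) -> tuple[OtuTable, GroundTruth]:
    """Draw one OTU table and its ground truth from a community spec.

    The table holds ``n_otus`` module members plus ``n_background``
    unstructured taxa (ids ``BG...``) that together carry
    ``background_share`` of the reads.  The background emulates the bulk
    of a real community that takes no part in the planted association
    structure: it damps the compositional closure term (whose common-mode
    variance would otherwise bias all correlations positive) and, being
    drawn with a wide abundance spread, supplies the rare low-prevalence
    taxa the 50%-prevalence filter is meant to remove.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _module_sizes(spec.n_otus, spec.n_modules)
    width = len(str(spec.n_otus - 1))
    otu_ids = [f"OTU{i:0{width}d}" for i in range(spec.n_otus)]

    module_of: dict[str, int] = {}
    signs = np.ones(spec.n_otus)
    loadings = np.empty(spec.n_otus)
    hubs: list[str] = []
    lo, hi = spec.loading_range
    pos = 0
    for b, size in enumerate(sizes):
        members = list(range(pos, pos + size))
        for i in members:
            module_of[otu_ids[i]] = b
        n_hubs = min(spec.hubs_per_module, size)
        n_reg = size - n_hubs
        # deterministic loading gradient over ordinary members
        grad = (
            np.linspace(lo, hi, n_reg) if n_reg > 1 else np.full(n_reg, hi)
        )
        loadings[members[n_hubs:]] = np.sqrt(spec.rho) * grad
        for i in members[:n_hubs]:
            loadings[i] = spec.hub_loading
            hubs.append(otu_ids[i])
        n_neg = _negative_count(size, spec.negative_fraction)
        if n_neg:
            # interleave sign flips across the loading gradient so the
            # planted sign ratio survives threshold-based edge recovery;
            # hubs stay positive
            stride = max(1, (size - n_hubs) // n_neg)
            flipped = members[n_hubs::stride][:n_neg]
            for i in flipped:
                signs[i] = -1.0
        pos += size

    # planted sign structure (zero across modules: independent factors)
    sign_mat = np.zeros((spec.n_otus, spec.n_otus))
    pos = 0
    for size in sizes:
        blk = slice(pos, pos + size)
        sign_mat[blk, blk] = np.outer(signs[blk], signs[blk])
        pos += size
    np.fill_diagonal(sign_mat, 0)

    # latent log-abundances
    factors = rng.normal(size=(spec.n_modules, spec.n_samples))
    eps = rng.normal(size=(spec.n_otus, spec.n_samples))
    module_idx = np.array([module_of[o] for o in otu_ids])
    a = loadings
    z = (
        signs[:, None] * a[:, None] * factors[module_idx]
        + np.sqrt(1.0 - a**2)[:, None] * eps
    )
    # OTU-specific mean abundances (kept identical across groups so alpha
    # diversity depends only on margins, not on the correlation structure)
    mean_rng = np.random.default_rng(10_007)  # fixed: margins shared by design
    base = np.maximum(
        mean_rng.normal(0.0, spec.base_abundance_sd, size=spec.n_otus),
        spec.base_abundance_floor,
    )
    for h in hubs:
        i = otu_ids.index(h)
        base[i] = max(base[i], spec.hub_min_abundance)

    # unstructured background: idiosyncratic latents, wide abundance spread,
    # scaled so the background carries `background_share` of expected mass
    n_bg = spec.n_background
    if n_bg > 0:
        bg_width = len(str(max(n_bg - 1, 1)))
        bg_ids = [f"BG{i:0{bg_width}d}" for i in range(n_bg)]
        bg_base = mean_rng.normal(0.0, spec.background_base_sd, size=n_bg)
        bg_z = rng.normal(size=(n_bg, spec.n_samples)) * spec.background_sd
        share = spec.background_share
        if share > 0:
            target = share / (1.0 - share) * np.exp(base).sum()
            bg_base += np.log(target / np.exp(bg_base).sum())
        otu_ids = otu_ids + bg_ids
        z = np.vstack([z, bg_z])
        base = np.concatenate([base, bg_base])
    n_total = len(otu_ids)

    abundance = np.exp(base[:, None] + z)
    composition = abundance / abundance.sum(axis=0, keepdims=True)

    counts = np.zeros((n_total, spec.n_samples), dtype=np.int64)
    for j in range(spec.n_samples):
        depth = spec.depth
        if spec.overdispersion > 0:
            depth = int(
                round(
                    np.exp(
                        np.log(spec.depth)
                        + rng.normal(0.0, spec.overdispersion)
                    )
                )
            )
        counts[:, j] = rng.multinomial(max(depth, 1), composition[:, j])
    if spec.zero_inflation > 0:
        mask = rng.random(counts.shape) < spec.zero_inflation
        counts[mask] = 0

    sample_ids = [f"S{j:02d}" for j in range(spec.n_samples)]
    counts_df = pd.DataFrame(
        counts, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids
    )
    taxonomy = pd.DataFrame(
        UNCLASSIFIED, index=counts_df.index, columns=list(RANKS)
    )
    taxonomy["kingdom"] = "Bacteria"
    taxonomy["phylum"] = [
        _PHYLA[module_of[o] % len(_PHYLA)]
        if o in module_of
        else _PHYLA[(spec.n_modules + i) % len(_PHYLA)]
        for i, o in enumerate(otu_ids)
    ]
    metadata = pd.DataFrame(
        {"group": ["G1"] * spec.n_samples, "timepoint": ["T1"] * spec.n_samples},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = OtuTable(counts=counts_df, taxonomy=taxonomy, metadata=metadata)
    full_sign = np.zeros((n_total, n_total))
    full_sign[: spec.n_otus, : spec.n_otus] = sign_mat
    full_loadings = np.concatenate([a * signs, np.zeros(n_total - spec.n_otus)])
    truth = GroundTruth(
        module_of=module_of,
        hubs=hubs,
        sign_matrix=pd.DataFrame(
            full_sign, index=counts_df.index, columns=counts_df.index
        ),
        loadings=pd.Series(full_loadings, index=counts_df.index),
        latents=pd.DataFrame(z, index=counts_df.index, columns=sample_ids),
        spec=spec,
    )
    return table, truth


def generate_goe_matrix(n: int, seed: int = 0) -> np.ndarray:
    """A Gaussian orthogonal ensemble matrix: symmetric, i.i.d. N(0,1)
    off-diagonal entries, doubled variance on the diagonal.  Its unfolded
    eigenvalue spacings follow the Wigner surmise."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, n))
    return (a + a.T) / np.sqrt(2.0)


def generate_block_matrix(
    n_blocks: int, block_size: int, seed: int = 0
) -> np.ndarray:
    """Block-diagonal matrix of independent GOE blocks; the superposed
    spectra give Poisson spacing statistics (the modular limit)."""
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    out = np.zeros((n, n))
    for b in range(n_blocks):
        a = rng.normal(size=(block_size, block_size))
        blk = slice(b * block_size, (b + 1) * block_size)
        out[blk, blk] = (a + a.T) / np.sqrt(2.0)
    return out


def generate_two_group_scenario(
    spec_a: CommunitySpec, spec_b: CommunitySpec | None = None
) -> tuple[tuple[OtuTable, GroundTruth], tuple[OtuTable, GroundTruth]]:
    """A control-vs-intervention pair where group B is better connected.

    If ``spec_b`` is omitted it copies ``spec_a`` with a higher
    within-module correlation and an upward-shifted loading gradient
    (denser network after thresholding) and a distinct seed; OTU mean
    abundances are shared, so composition margins are matched between
    arms while network density differs.
    """
    if spec_b is None:
        lo, hi = spec_a.loading_range
        spec_b = CommunitySpec(
            **{
                **spec_a.__dict__,
                "rho": min(0.95, spec_a.rho + 0.2),
                "loading_range": (min(lo + 0.15, 1.0), min(hi + 0.1, 1.0)),
                "seed": spec_a.seed + 500_000,
            }
        )
    a = generate_community(spec_a)
    b = generate_community(spec_b)
    a[0].metadata["group"] = "A"
    b[0].metadata["group"] = "B"
    b[0].counts.columns = [f"B{s}" for s in b[0].counts.columns]
    b[0].metadata.index = pd.Index(
        [f"B{s}" for s in b[0].metadata.index], name="sample_id"
    )
    return a, b
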