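"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`generate_seed_image` renders a rotated superellipse silhouette
  (|x/a|^n + |y/b|^n <= 1) as a bright-on-dark grayscale image.  The
  family is chosen because its area has the closed form
  ``A = 4ab * Gamma(1+1/n)^2 / Gamma(1+2/n)`` (the ellipse pi*a*b at n=2)
  and, for n >= 1, it is convex with Feret = 2*max(a,b) and
  Breadth = 2*min(a,b) — analytic ground truth without real seed photos.

* :func:`generate_genotype_panel` draws a structured biallelic SNP panel:
  subpopulation allele frequencies follow the Balding-Nichols model
  (Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst) around an ancestral frequency p),
  and linkage disequilibrium is induced by a Gaussian-copula AR(1) along
  each chromosome with correlation exp(-d/L) at map distance d, so the
  expected r^2 declines smoothly with cM distance.

* :func:`simulate_phenotypes` draws a genotype x environment x replicate
  phenotype table ``y_ijk = mu + E_j + sum_q a_q x_iq (+ QTN-by-env
  deviations) + g_i + (gE)_ij + rep_k(j) + eps_ijk`` with stated variance
  components, plus a thousand-kernel weight coupled to the focal trait at
  a chosen correlation. The defaults mirror a two-environment
  (well-watered / rain-fed), two-replicate wheat trial.

All randomness flows through one integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gamma as _gamma

from .popgen import GenotypePanel
from .segmentation import SeedImage

__all__ = [
    "ShapeParams",
    "PanelSpec",
    "QTN",
    "PhenoSpec",
    "WHEAT_CHROMOSOMES",
    "superellipse_area",
    "generate_seed_image",
    "generate_genotype_panel",
    "simulate_phenotypes",
]

#: The 21 bread-wheat chromosomes with their subgenome class.
WHEAT_CHROMOSOMES = [(f"{i}{g}", g) for i in range(1, 8) for g in "ABD"]


@dataclass
class ShapeParams:
    """Superellipse silhouette: semi-axes (mm), order n, rotation (deg)."""

    a: float = 3.4        # semi-major axis, mm (wheat seed length ~ 7 mm)
    b: float = 1.6        # semi-minor axis, mm
    n: float = 2.0        # superellipse order; 2 = ellipse
    rotation: float = 0.0  # degrees, counter-clockwise
    offset: tuple[float, float] = (0.0, 0.0)  # centroid offset, mm

    def __post_init__(self):
        if min(self.a, self.b) <= 0 or self.n <= 0:
            raise ValueError("semi-axes and exponent must be > 0")


def superellipse_area(a: float, b: float, n: float) -> float:
    """Closed-form area 4ab * Gamma(1+1/n)^2 / Gamma(1+2/n)."""
    return 4.0 * a * b * _gamma(1.0 + 1.0 / n) ** 2 / _gamma(1.0 + 2.0 / n)


def generate_seed_image(
    params: ShapeParams,
    scale: float = 0.02,
    noise_sd: float = 0.0,
    seed: int = 0,
    canvas: tuple[int, int] | None = None,
    margin_mm: float = 0.5,
    foreground: float = 200.0,
    background: float = 10.0,
    view: str = "dorsal",
) -> tuple[SeedImage, dict]:
    """Render one silhouette and return it with its analytic geometry.

    ``scale`` is mm per pixel.  The ground-truth dict carries the closed-form
    area and (for n >= 1, convex) Feret/Breadth from the semi-axes.
    Raises if the scale is non-positive or the shape does not fit the canvas.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0 mm/px")
    a, b, n = params.a, params.b, params.n
    # outermost point of a superellipse is within the (a, b) corner radius
    halfwidth = float(np.hypot(a, b)) + margin_mm
    if canvas is None:
        side = int(np.ceil(2.0 * halfwidth / scale)) + 1
        canvas = (side, side)
    rows, cols = canvas
    cy, cx = (rows - 1) / 2.0 * scale, (cols - 1) / 2.0 * scale
    y, x = np.mgrid[0:rows, 0:cols].astype(float) * scale
    x = x - cx - params.offset[0]
    y = y - cy - params.offset[1]
    th = np.deg2rad(params.rotation)
    xr = np.cos(th) * x + np.sin(th) * y
    yr = -np.sin(th) * x + np.cos(th) * y
    inside = (np.abs(xr / a) ** n + np.abs(yr / b) ** n) <= 1.0
    # the shape must sit strictly inside the canvas
    edge = np.concatenate([inside[0], inside[-1], inside[:, 0], inside[:, -1]])
    if edge.any() or not inside.any():
        raise ValueError("shape exceeds the image canvas; enlarge it")
    img = np.where(inside, foreground, background).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = {
        "area": superellipse_area(a, b, n),
        "feret": 2.0 * max(a, b) if n >= 1 else np.nan,
        "breadth": 2.0 * min(a, b) if n >= 1 else np.nan,
        "convex": n >= 1,
    }
    return SeedImage(pixels=img, scale=scale, view=view), truth


@dataclass
class PanelSpec:
    """Structured SNP panel: sizes, map, subpopulation structure and LD."""

    n_accessions: int = 300
    markers_per_chromosome: int = 50
    chromosomes: list = field(default_factory=lambda: list(WHEAT_CHROMOSOMES))
    map_length_cm: float = 150.0
    n_subpops: int = 3
    fst: float = 0.2
    maf_floor: float = 0.01
    ld_block_cm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fst < 1:
            raise ValueError("F_ST must be in (0, 1)")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("MAF floor must be in (0, 0.5)")
        if min(self.n_accessions, self.markers_per_chromosome,
               self.n_subpops) < 1 or self.map_length_cm <= 0 \
                or self.ld_block_cm <= 0:
            raise ValueError("all counts/lengths must be positive")


def _strict_increasing_positions(rng, m, length):
    while True:
        pos = np.sort(rng.uniform(0.0, length, m))
        if m < 2 or (np.diff(pos) > 0).all():
            return pos


def generate_genotype_panel(spec: PanelSpec) -> GenotypePanel:
    """Draw a panel under Balding-Nichols structure with AR(1)-copula LD.

    Every marker's realized minor-allele frequency is at least
    ``spec.maf_floor``; violating columns are redrawn (independently of
    their neighbours) up to 100 times before an error naming the marker.
    """
    rng = np.random.default_rng(spec.seed)
    n, K = spec.n_accessions, spec.n_subpops
    subpop = rng.permutation(np.arange(n) % K)
    n_hap = 2 * n

    chrom_labels, genomes, cms = [], [], []
    for label, genome in spec.chromosomes:
        pos = _strict_increasing_positions(rng, spec.markers_per_chromosome,
                                           spec.map_length_cm)
        chrom_labels += [label] * len(pos)
        genomes += [genome] * len(pos)
        cms.append(pos)
    cms = np.concatenate(cms)
    m = len(cms)

    p_anc = rng.uniform(spec.maf_floor, 1.0 - spec.maf_floor, m)
    shape = (1.0 - spec.fst) / spec.fst
    # Balding-Nichols subpopulation frequencies, K x m
    p_sub = rng.beta(np.maximum(p_anc * shape, 1e-6),
                     np.maximum((1.0 - p_anc) * shape, 1e-6), size=(K, m))
    p_sub = np.clip(p_sub, 1e-4, 1.0 - 1e-4)

    hap_sub = np.repeat(subpop, 2)
    dosages = np.empty((n, m), dtype=np.int8)
    # copula latent field, chromosome by chromosome
    col = 0
    for label, _ in spec.chromosomes:
        mc = spec.markers_per_chromosome
        pos = cms[col:col + mc]
        Z = np.empty((n_hap, mc))
        Z[:, 0] = rng.standard_normal(n_hap)
        for j in range(1, mc):
            rho = np.exp(-(pos[j] - pos[j - 1]) / spec.ld_block_cm)
            Z[:, j] = rho * Z[:, j - 1] + np.sqrt(1 - rho**2) * \
                rng.standard_normal(n_hap)
        U = stats.norm.cdf(Z)
        alleles = (U < p_sub[hap_sub, col:col + mc]).astype(np.int8)
        dosages[:, col:col + mc] = alleles[0::2] + alleles[1::2]
        col += mc

    # enforce the MAF floor marker by marker
    maf = np.minimum(dosages.mean(axis=0) / 2.0,
                     1.0 - dosages.mean(axis=0) / 2.0)
    for j in np.flatnonzero(maf < spec.maf_floor):
        ok = False
        for _ in range(100):
            p_j = rng.uniform(max(spec.maf_floor * 2, 0.05), 0.5)
            ps = np.clip(rng.beta(p_j * shape, (1 - p_j) * shape, K),
                         1e-4, 1 - 1e-4)
            alle = (rng.random(n_hap) < ps[hap_sub]).astype(np.int8)
            d = alle[0::2] + alle[1::2]
            f = d.mean() / 2.0
            if min(f, 1 - f) >= spec.maf_floor:
                dosages[:, j] = d
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"MAF floor {spec.maf_floor} unreachable for marker rs{j}")

    markers = pd.DataFrame({
        "id": [f"rs{i}" for i in range(m)],
        "chrom": chrom_labels,
        "genome": genomes,
        "cm": cms,
    })
    accessions = pd.DataFrame({
        "id": [f"acc{i:04d}" for i in range(n)],
        "subpop": subpop,
        "class": np.where(subpop == 0, "cultivar", "landrace"),
    })
    return GenotypePanel(dosages=dosages, markers=markers,
                         accessions=accessions)


@dataclass
class QTN:
    """One planted causal marker: additive effect per alternate allele, with
    an optional per-environment deviation added to the main effect."""

    marker: str
    effect: float
    env_deviation: tuple | None = None


@dataclass
class PhenoSpec:
    """Two-environment, replicated phenotype simulation settings.

    Variance components are in squared trait units.  When ``target_h2`` is
    set, the genotypic variance is derived from the other components so
    that the entry-mean broad-sense heritability
    ``H2 = s2_g / (s2_g + s2_ge/e + s2_e/(e r))`` hits the target exactly
    in expectation.
    """

    qtns: list = field(default_factory=list)
    env_means: tuple = (38.92, 28.38)   # focal-trait mean per environment
    n_reps: int = 2
    target_h2: float | None = 0.8
    var_g: float = 7.0
    var_ge: float = 2.0
    var_rep: float = 0.5
    var_e: float = 3.0
    trait_name: str = "Volume"
    tkw_coupling: float = 0.8           # within-env corr(TKW, focal trait)
    tkw_means: tuple = (42.10, 28.18)
    tkw_sd: float = 2.0

    def __post_init__(self):
        if min(self.var_g, self.var_ge, self.var_rep, self.var_e) < 0:
            raise ValueError("variance shares must be >= 0")
        if self.target_h2 is not None and not 0 <= self.target_h2 <= 1:
            raise ValueError("target H^2 must be in [0, 1]")
        if len(self.env_means) < 2 or self.n_reps < 2:
            raise ValueError("need >= 2 environments and >= 2 replicates")
        if not -1 <= self.tkw_coupling <= 1:
            raise ValueError("TKW coupling must be a correlation in [-1, 1]")

    def resolved_var_g(self) -> float:
        if self.target_h2 is None:
            return self.var_g
        e, r = len(self.env_means), self.n_reps
        denom = self.var_ge / e + self.var_e / (e * r)
        if self.target_h2 >= 1.0:
            if denom > 0:
                raise ValueError("H^2 = 1 needs zero non-genetic variance")
            return self.var_g
        return self.target_h2 / (1.0 - self.target_h2) * denom


def simulate_phenotypes(panel: GenotypePanel, spec: PhenoSpec,
                        seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate the replicated two-environment phenotype table.

    Returns a long table (accession, env, rep, trait, value) holding the
    focal trait and TKW, plus a truth record (genotypic values, variance
    components, expected H^2) for recovery tests.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_accessions
    e, r = len(spec.env_means), spec.n_reps
    var_g = spec.resolved_var_g()

    marker_index = {mid: j for j, mid in enumerate(panel.markers["id"])}
    qtn_main = np.zeros(n)
    qtn_env = np.zeros((n, e))
    for q in spec.qtns:
        if q.marker not in marker_index:
            raise KeyError(f"QTN marker {q.marker!r} not in panel")
        x = panel.dosages[:, marker_index[q.marker]].astype(float)
        qtn_main += q.effect * x
        if q.env_deviation is not None:
            dev = np.asarray(q.env_deviation, float)
            if len(dev) != e:
                raise ValueError("env_deviation length must match environments")
            qtn_env += np.outer(x, dev)

    g = rng.normal(0.0, np.sqrt(var_g), n)
    ge = rng.normal(0.0, np.sqrt(spec.var_ge), (n, e))
    rep_eff = rng.normal(0.0, np.sqrt(spec.var_rep), (e, r))
    eps = rng.normal(0.0, np.sqrt(spec.var_e), (n, e, r))

    mu = np.asarray(spec.env_means, float)
    y = (mu[None, :, None] + (qtn_main + g)[:, None, None]
         + (qtn_env + ge)[:, :, None] + rep_eff[None, :, :] + eps)

    # TKW coupled to the focal trait within each environment
    tkw = np.empty_like(y)
    rho = spec.tkw_coupling
    for j in range(e):
        yj = y[:, j, :]
        sd = yj.std() if yj.std() > 0 else 1.0
        z = (yj - yj.mean()) / sd
        noise = rng.standard_normal(z.shape)
        tkw[:, j, :] = spec.tkw_means[j % len(spec.tkw_means)] + \
            spec.tkw_sd * (rho * z + np.sqrt(1.0 - rho**2) * noise)

    acc = panel.accessions["id"].to_numpy()
    ii, jj, kk = np.meshgrid(np.arange(n), np.arange(e), np.arange(r),
                             indexing="ij")
    base = {
        "accession": acc[ii.ravel()],
        "env": np.asarray([f"env{j + 1}" for j in range(e)])[jj.ravel()],
        "rep": kk.ravel() + 1,
    }
    long = pd.concat([
        pd.DataFrame({**base, "trait": spec.trait_name, "value": y.ravel()}),
        pd.DataFrame({**base, "trait": "TKW", "value": tkw.ravel()}),
    ], ignore_index=True)

    truth = {
        "g": g,
        "qtn_main": qtn_main,
        "var_g": var_g,
        "var_ge": spec.var_ge,
        "var_rep": spec.var_rep,
        "var_e": spec.var_e,
        "expected_h2": var_g / (var_g + spec.var_ge / e
                                + spec.var_e / (e * r))
        if (var_g + spec.var_ge + spec.var_e) > 0 else np.nan,
        "e": e,
        "r": r,
    }
    return long, truth
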