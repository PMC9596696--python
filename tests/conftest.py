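import numpy as np
import pytest

from seedgwas import popgen, synthetic


@pytest.fixture(scope="session")
def structured_panel():
    """300 accessions, 3 subpopulations at F_ST = 0.4, 6 chromosomes."""
    spec = synthetic.PanelSpec(
        n_accessions=300, markers_per_chromosome=30,
        chromosomes=synthetic.WHEAT_CHROMOSOMES[:6], fst=0.4, seed=11)
    return synthetic.generate_genotype_panel(spec)


@pytest.fixture(scope="session")
def default_panel():
    """Default-condition panel: 300 accessions, 21 chromosomes."""
    spec = synthetic.PanelSpec(n_accessions=300, markers_per_chromosome=20,
                               seed=5)
    return synthetic.generate_genotype_panel(spec)


@pytest.fixture(scope="session")
def kinship_scores(structured_panel):
    K = popgen.kinship_vanraden(structured_panel)
    vals, scores, pct = popgen.pca_genotypes(K)
    return K, scores, pct


def random_convex_polygon(rng, n_points=40, radius=5.0):
    """Convex polygon (CCW vertex array) from the hull of random points."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(scale=radius, size=(n_points, 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]
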