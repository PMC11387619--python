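import numpy as np
import pytest

import strainvar as sv


@pytest.fixture(scope="session")
def small_db():
    """12 genes x 3 equal-length alleles, 1% divergence."""
    return sv.make_synthetic_db(
        n_genes=12, gene_len=300, alleles_per_gene=3, divergence=0.01, seed=101
    )


@pytest.fixture(scope="session")
def dual_strains(small_db):
    genes = small_db.gene_ids()
    majority = sv.StrainSpec("majA", {g: "1" for g in genes})
    minority = sv.StrainSpec("minB", {g: "2" for g in genes})
    return majority, minority


@pytest.fixture(scope="session")
def clean_sample(small_db, dual_strains):
    """Noise-free 95/5 dual-strain mix at 200x."""
    mix = sv.MixSpec(list(dual_strains), [0.95, 0.05], depth=200, seed=202)
    return sv.simulate_sample(mix, small_db, sv.ErrorModel.noise_free())


@pytest.fixture(scope="session")
def noisy_sample(small_db, dual_strains):
    """Default error model, 93/7 dual-strain mix at 220x."""
    mix = sv.MixSpec(list(dual_strains), [0.93, 0.07], depth=220, seed=303)
    return sv.simulate_sample(mix, small_db, sv.ErrorModel())


def random_variant_map(rng, n_genes=3, gene_len=80, depth=120):
    """A random VariantMap with a dominant consensus and scattered minorities."""
    db = sv.make_synthetic_db(n_genes, gene_len, 2, 0.02, seed=int(rng.integers(2**31)))
    vmap = sv.VariantMap()
    from strainvar.pileup import BASE_INDEX, GenePileup

    for gene_id in db.gene_ids():
        template = db.get(gene_id, "1").sequence
        counts = np.zeros((gene_len, 5), dtype=np.int64)
        for pos, base in enumerate(template):
            counts[pos, BASE_INDEX[base]] = depth
        # sprinkle minority observations at random cells
        for _ in range(int(rng.integers(3, 12))):
            pos = int(rng.integers(gene_len))
            alt = int(rng.integers(4))
            take = int(rng.integers(1, depth // 4))
            major = BASE_INDEX[template[pos]]
            if alt == major:
                continue
            counts[pos, major] -= take
            counts[pos, alt] += take
        vmap.genes[gene_id] = GenePileup(gene_id, "1", template, counts)
    return vmap, db
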