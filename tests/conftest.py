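import numpy as np
import pytest

from ssr_atlas.simulate import PlantSpec, SimConfig, generate

_BASES = np.array(list("ACGT"))


def random_sequence(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(_BASES[rng.choice(4, size=n, p=list(p))])


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A written synthetic genome bundle with a mixed plant composition."""
    cfg = SimConfig(
        seed=11, n_chroms=2, chrom_length_bp=300_000, n_fraction=0.04,
        plants=(
            PlantSpec(count=60, motif_size=1, unit_count=(12, 40),
                      region="intergenic"),
            PlantSpec(count=60, motif_size=2, unit_count=(7, 30),
                      region="intron"),
            PlantSpec(count=30, motif_size=3, unit_count=(5, 15),
                      region="exon"),
            PlantSpec(count=30, motif_size=4, unit_count=(4, 10),
                      region="any"),
            PlantSpec(count=10, motif="AATGC", unit_count=4,
                      region="intron"),
            PlantSpec(count=10, motif="ACGTAC", unit_count=4,
                      region="intergenic"),
        ),
    )
    outdir = tmp_path_factory.mktemp("sim_bundle")
    return generate(cfg, outdir=outdir)
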