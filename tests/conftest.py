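import pandas as pd
import pytest

from herbdiv.design import MatingDesign, build_design
from herbdiv.pipeline import make_fixture, run
from herbdiv.simulate import make_locus_panel, simulate_genotypes


@pytest.fixture(scope="session")
def mating4() -> MatingDesign:
    return MatingDesign(n_mothers=4)


@pytest.fixture(scope="session")
def panel11():
    """11 loci with 11 equifrequent alleles each (the calibration panel)."""
    return make_locus_panel(n_loci=11, n_alleles=11, seed=2, equifrequent=True)


@pytest.fixture(scope="session")
def cohort(mating4, panel11):
    """Error-free 2-block, 4-family cohort: (design, genotypes)."""
    design = build_design(2, mating4, seed=5)
    genotypes = simulate_genotypes(design, panel11, mating4, seed=5)
    return design, genotypes


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Artifacts of a full pipeline run on the small standard fixture."""
    outdir = tmp_path_factory.mktemp("small_run")
    return run(make_fixture("small"), outdir), outdir


@pytest.fixture()
def perfect_maternity():
    """Maternity table builder that trusts the design's true families."""

    def build(design: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offspring_id": design["sapling_id"],
                "best_mother": design["family"],
                "mismatches": 0,
                "status": "assigned",
            }
        )

    return build
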