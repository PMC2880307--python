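import pandas as pd
import pytest

import panelgen as pg


@pytest.fixture
def study_design():
    """The default panel layout: 40 lines x 2 sexes x 10 replicate vials."""
    return pg.ExperimentDesign()


@pytest.fixture
def heritable_tv():
    """Variance components giving true H2 = 0.6 with a visible sex effect."""
    return pg.TrueVariances(
        grand_mean=10.0, sex_effect=1.0,
        sigma2_line=2.0, sigma2_line_sex=1.0, sigma2_error=1.0,
    )


@pytest.fixture
def panel_pheno(study_design, heritable_tv):
    return pg.simulate_phenotypes(study_design, heritable_tv, seed=1)


def make_pheno(values_by_cell, trait="trait"):
    """Build a tidy phenotype table from {(line, sex): [replicate values]}."""
    rows = []
    for (line, sex), vals in values_by_cell.items():
        for k, v in enumerate(vals):
            rows.append((line, sex, f"V{k + 1:02d}", float(v)))
    return pd.DataFrame(rows, columns=["line", "sex", "vial", trait])


@pytest.fixture
def toy_pheno_2x2x2():
    """Hand-enumerable 2-line x 2-sex x 2-vial table."""
    return make_pheno({
        ("L1", "female"): [10.0, 12.0],
        ("L1", "male"): [11.0, 15.0],
        ("L2", "female"): [20.0, 22.0],
        ("L2", "male"): [19.0, 23.0],
    })
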