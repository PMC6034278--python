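import pytest

from ltrfunc.synthetic_chip import SimParams, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Default-condition synthetic dataset, laptop scale, fixed seed."""
    params = SimParams(
        seed=101,
        n_loci={"HERV_prototypes": 500, "HERV_Dfam": 400, "MaLR_Dfam": 400, "gene": 150},
    )
    records, truth, sheet, matrix = simulate(params)
    return {"params": params, "records": records, "truth": truth,
            "sheet": sheet, "matrix": matrix}
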