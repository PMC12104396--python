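import pytest

from cypscreen import builtin_profiles
from cypscreen.simulate import KineticParams, simulate_plate

# Published per-drug summary columns used as fixed inputs throughout the
# suite: total IC50 (µM), unbound IC50 (µM), unbound Ki (µM), unbound Cmax
# (µg/mL and µM), and the ratio figure as printed.
PUBLISHED_TABLE = {
    "Omeprazole":   {"ic50": 1.41, "ic50_u": 70.5,  "ki_u": 35.25,
                     "cmax_u_ug": 0.0112, "cmax_u_um": 0.0324, "printed_ratio": 0.0288},
    "Lansoprazole": {"ic50": 1.65, "ic50_u": 82.5,  "ki_u": 41.25,
                     "cmax_u_ug": 0.0115, "cmax_u_um": 0.0311, "printed_ratio": 0.00332},
    "Pantoprazole": {"ic50": 3.52, "ic50_u": 176.0, "ki_u": 88.0,
                     "cmax_u_ug": 0.025,  "cmax_u_um": 0.0652, "printed_ratio": 0.00124},
    "Rabeprazole":  {"ic50": 6.43, "ic50_u": 321.5, "ki_u": 160.75,
                     "cmax_u_ug": 0.0062, "cmax_u_um": 0.0173, "printed_ratio": 0.000635},
    "Ilaprazole":   {"ic50": 6.62, "ic50_u": 331.0, "ki_u": 165.5,
                     "cmax_u_ug": 0.0045, "cmax_u_um": 0.0123, "printed_ratio": 0.00224},
}

POTENCY_ORDER = ["Omeprazole", "Lansoprazole", "Pantoprazole",
                 "Rabeprazole", "Ilaprazole"]


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def noiseless_plate():
    return simulate_plate(
        [("DrugA", 2.0), ("DrugB", 6.0)],
        params=KineticParams(noise_cv=0.0), seed=3, plate_id="P0",
    )


@pytest.fixture(scope="session")
def noisy_plate():
    return simulate_plate(
        [("DrugA", 2.0), ("DrugB", 6.0)],
        params=KineticParams(), seed=3, plate_id="P1",
    )
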