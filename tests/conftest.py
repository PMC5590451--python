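import pytest

from nsfdpk import SUBJECTS, build_error_table

# Reference benchmark: max absolute node errors of the forward-Euler scheme
# against the closed form, Subject 1, T = 20 min, doubling ladder.
SFD_BOLUS_CENTRAL = {
    2: 0.144913386, 4: 0.053199386, 8: 0.024396686, 16: 0.011669111,
    32: 0.005719559, 64: 0.002831162, 128: 0.001408639, 256: 0.000702591,
    512: 0.000350865, 1024: 0.000175326,
}
SFD_BOLUS_PERIPHERAL = {
    2: 0.126270717, 4: 0.046283217, 8: 0.021180830, 16: 0.010127446,
    32: 0.004961080, 64: 0.002455508, 128: 0.001221609, 256: 0.000609284,
    512: 0.000304265, 1024: 0.000152038,
}
SFD_INFUSION_CENTRAL = {
    2: 1.98326261, 4: 0.73839463, 8: 0.34211236, 16: 0.16473051,
    32: 0.08083009, 64: 0.04005593, 128: 0.01993844, 256: 0.00994725,
    512: 0.00496814, 1024: 0.00248270,
}
SFD_INFUSION_PERIPHERAL = {
    2: 1.57898904, 4: 0.56648904, 8: 0.25172781, 16: 0.12005326,
    32: 0.05860324, 64: 0.02895478, 128: 0.01439233, 256: 0.00717515,
    512: 0.00358234, 1024: 0.00178986,
}


@pytest.fixture(scope="session")
def subject1():
    return SUBJECTS[1].params


@pytest.fixture(scope="session")
def ladder_tables(subject1):
    """All four benchmark error tables, built once per session."""
    return {
        ("bolus", "central"): build_error_table("bolus", subject1, compartment="central"),
        ("bolus", "peripheral"): build_error_table("bolus", subject1, compartment="peripheral"),
        ("infusion", "central"): build_error_table("infusion", subject1, I0=1.0, compartment="central"),
        ("infusion", "peripheral"): build_error_table("infusion", subject1, I0=1.0, compartment="peripheral"),
    }
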