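"""Built-in subject parameter sets and random parameter generation.

The four built-in subjects carry sisomicin rate constants estimated from a
two-compartment open-model analysis of serum concentrations after I.V.
administration; they drive every benchmark in this package (the numerical
error ladders use Subject 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PKParameters

__all__ = ["SubjectFixture", "SUBJECTS", "random_parameter_fixture"]


@dataclass(frozen=True)
class SubjectFixture:
    label: str
    params: PKParameters
    D: float  # dose rate, mg/min


SUBJECTS: dict[int, SubjectFixture] = {
    1: SubjectFixture("Subject 1", PKParameters(k10=0.00940, k12=0.04050, k21=0.02910), D=1.0),
    2: SubjectFixture("Subject 2", PKParameters(k10=0.01110, k12=0.02504, k21=0.02230), D=1.0),
    3: SubjectFixture("Subject 3", PKParameters(k10=0.01030, k12=0.02750, k21=0.02830), D=1.0),
    4: SubjectFixture("Subject 4", PKParameters(k10=0.01520, k12=0.04120, k21=0.02410), D=1.0),
}


def random_parameter_fixture(
    seed: int,
    n_sets: int = 100,
    rate_range: tuple[float, float] = (1e-3, 1e-1),
) -> list[PKParameters]:
    """Reproducible log-uniform random rate constants for property tests.

    The default range [1e-3, 1e-1] min^-1 brackets the built-in subject
    values. All three rates are drawn strictly positive, so every returned
    set is admissible.
    """
    lo, hi = rate_range
    if not (0 < lo < hi):
        raise ValueError("rate_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_sets, 3)))
    return [PKParameters(k10=float(a), k12=float(b), k21=float(c)) for a, b, c in draws]
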