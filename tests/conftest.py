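import numpy as np
import pytest

from terrapop.encounter_io import EncounterHistorySet, Individual, Occasion


def make_set(histories, sexes=None, years=None, effort=None, hurricane=None):
    """Build an EncounterHistorySet from history strings like "101"."""
    k = len(histories[0])
    if years is None:
        years = list(range(2001, 2001 + k))
    if sexes is None:
        sexes = ["female"] * len(histories)
    if effort is None:
        effort = [0.0] * k
    if hurricane is None:
        hurricane = [False] * k
    occ = [Occasion(y, e, h) for y, e, h in zip(years, effort, hurricane)]
    inds = [
        Individual(f"i{j}", s, tuple(int(c) for c in h))
        for j, (h, s) in enumerate(zip(histories, sexes))
    ]
    return EncounterHistorySet(occ, inds)


def cjs_probability_oracle(ehs, phi_annual, p):
    """Brute-force CJS likelihood by enumerating each animal's death time.

    ``phi_annual[sex][t]`` is annual survival for interval t and
    ``p[sex][j]`` detection at occasion j (j >= 1); both indexed 0=female,
    1=male.  Interval survival is phi ** dt.  Returns the product over
    individuals of P(history | first capture).
    """
    years = ehs.years
    dt = np.diff(years)
    total = 1.0
    for ind in ehs.individuals:
        s = 0 if ind.sex == "female" else 1
        y = ind.detections
        k = len(y)
        f = ind.first_detection
        last = ind.last_detection
        prob = 0.0
        # alive through occasion a (f <= a <= k-1), dead in interval a->a+1
        for a in range(last, k):
            pr = 1.0
            for t in range(f, a):
                pr *= phi_annual[s][t] ** dt[t]
            if a < k - 1:
                pr *= 1.0 - phi_annual[s][a] ** dt[a]
            for j in range(f + 1, a + 1):
                pr *= p[s][j] if y[j] == 1 else 1.0 - p[s][j]
            prob += pr
        total *= prob
    return total


@pytest.fixture
def three_occasion_set():
    return make_set(["101", "011", "110"])
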