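import pytest

from causalsel import default_config, generate_ratings


def brute_force_outcome_probs(kind: str, p_f: float, p_a: float) -> dict:
    """Independent enumeration oracle over the four cause assignments.

    Deliberately avoids the package's own world machinery: plain loops and
    inline truth functions.
    """
    p_E = p_C = p_E_and_C = p_E_and_notC = 0.0
    for f in (0, 1):
        for a in (0, 1):
            w = (p_f if f else 1 - p_f) * (p_a if a else 1 - p_a)
            e = (f and a) if kind == "conjunctive" else (f or a)
            if e:
                p_E += w
                if f:
                    p_E_and_C += w
                else:
                    p_E_and_notC += w
            if f:
                p_C += w
    out = {"p_E": p_E, "p_E_given_C": p_E_and_C / p_C}
    if 1 - p_C > 1e-12:
        out["p_E_given_notC"] = p_E_and_notC / (1 - p_C)
    return out


@pytest.fixture(scope="session")
def exp1_table():
    """One synthetic conjunctive dataset at the shipped defaults."""
    return generate_ratings(default_config("exp1_conjunctive", seed=0))


@pytest.fixture(scope="session")
def exp2_table():
    """One synthetic disjunctive dataset at the shipped defaults."""
    return generate_ratings(default_config("exp2_disjunctive", seed=0))
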