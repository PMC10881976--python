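import itertools

import numpy as np
import pytest

import bicarbenv as bv
from bicarbenv.model import stoichiometric_matrix


@pytest.fixture(scope="session")
def core_model():
    return bv.build_core_model()


@pytest.fixture(scope="session")
def core_with_pathway(core_model):
    return bv.add_3hp_pathway(core_model)


@pytest.fixture(scope="session")
def toy_branch():
    return bv.build_toy_branch_model()


@pytest.fixture(scope="session")
def toy_linear():
    return bv.build_toy_linear_model()


def brute_force_optimum(model, objective, sense="max"):
    """Independent LP oracle for tiny models: enumerate candidate vertices of
    {S v = 0, lb <= v <= ub} by fixing (n - rank S) fluxes at a bound and
    solving the linear system for the rest; return the best feasible
    objective.  Exponential; only for models with <= 8 reactions."""
    S = stoichiometric_matrix(model).toarray()
    rids = model.reaction_ids
    n = len(rids)
    assert n <= 8, "oracle is exponential; use tiny models only"
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    rank = np.linalg.matrix_rank(S)
    k = n - rank
    j_obj = rids.index(objective)
    best = None
    for fixed_idx in itertools.combinations(range(n), k):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        if np.linalg.matrix_rank(A) < len(free_idx):
            continue
        for bits in itertools.product((0, 1), repeat=k):
            v = np.zeros(n)
            for j, bit in zip(fixed_idx, bits):
                v[j] = lb[j] if bit == 0 else ub[j]
            b = -S[:, list(fixed_idx)] @ v[list(fixed_idx)] if k else np.zeros(S.shape[0])
            x, *_ = np.linalg.lstsq(A, b, rcond=None)
            v[free_idx] = x
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            val = v[j_obj]
            if best is None or (sense == "max" and val > best) or (
                    sense == "min" and val < best):
                best = val
    assert best is not None, "oracle found no feasible vertex"
    return best
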