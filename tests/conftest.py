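import numpy as np
import pandas as pd
import pytest

from isnkit import (
    BlockerEfficacy,
    DoseResponseDataset,
    TimeConstants,
    TransferFunctionSpec,
    TwoPopParams,
    fixed_point,
)
from isnkit.inference import predict_rates
from isnkit.synth import v1_best_fit_params


@pytest.fixture(scope="session")
def vgat_params() -> TwoPopParams:
    """Published best-fit parameters for V1 whole-population stimulation."""
    return v1_best_fit_params()


@pytest.fixture(scope="session")
def vgat_taus() -> TimeConstants:
    return TimeConstants(7.8, 34.3)


def random_stable_isn(rng, require_isn=None):
    """Draw a random stable parameter set with an interior resting point.

    ``require_isn``: None (any), True (W_EE > 1), False (W_EE < 1).
    Rejection sampling; all draws have D > 0 and both rates positive at
    L = 0.
    """
    while True:
        if require_isn is True:
            wee = rng.uniform(1.1, 4.0)
        elif require_isn is False:
            wee = rng.uniform(0.0, 0.9)
        else:
            wee = rng.uniform(0.0, 4.0)
        p = TwoPopParams(
            W_EE=wee,
            W_EI=rng.uniform(0.5, 4.0),
            W_IE=rng.uniform(0.5, 10.0),
            W_II=rng.uniform(0.5, 10.0),
            I_EX=rng.uniform(1.0, 15.0),
            I_IX=rng.uniform(1.0, 40.0),
            lam=rng.uniform(0.5, 10.0),
            tf_E=TransferFunctionSpec(x0=rng.uniform(0.0, 3.0)),
            tf_I=TransferFunctionSpec(x0=rng.uniform(0.0, 10.0)),
        )
        if p.determinant <= 0.1:
            continue
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fp = fixed_point(p, 0.0)
        if fp.branch == "interior" and fp.r_E > 0.5 and fp.r_I > 0.5:
            return p


def make_noiseless_dataset(
    truth: TwoPopParams,
    eps: BlockerEfficacy = BlockerEfficacy(0.3, 0.3),
    sessions=("s0", "s1"),
    intensities=None,
) -> DoseResponseDataset:
    """Noiseless three-phase population curves generated from ``truth``."""
    L = np.linspace(0.0, 3.0, 10) if intensities is None else intensities
    rows = []
    for phase in ("intact", "e_blocked", "ei_blocked"):
        for sess in ["pooled"] if phase == "intact" else list(sessions):
            for pop in ("E", "I"):
                r = predict_rates(truth, eps, phase, L, pop)
                rows += [
                    dict(session=sess, phase=phase, population=pop,
                         intensity=li, rate=ri)
                    for li, ri in zip(L, r)
                ]
    return DoseResponseDataset(pd.DataFrame(rows))
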