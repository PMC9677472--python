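import numpy as np
import pandas as pd
import pytest

import trsnmatch as tm


@pytest.fixture(scope="session")
def small_spec() -> tm.SimulationSpec:
    return tm.SimulationSpec(n_genes=300, n_chroms=2, seed=11)


@pytest.fixture(scope="session")
def planted_condition(small_spec):
    """One synthetic condition: annotation, TF, planted targets, peaks, expression."""
    ann = tm.gen_annotation(small_spec)
    genes = list(ann.index)
    tf, planted = genes[0], genes[1:31]
    directions = {g: ("up" if i % 2 == 0 else "down")
                  for i, g in enumerate(planted)}
    peaks, expr = tm.gen_condition(small_spec, tf, planted, directions, ann)
    return ann, tf, planted, directions, peaks, expr


@pytest.fixture(scope="session")
def tiny_library():
    """A 35-column synthetic library (5 up/down pairs merged) for matching tests."""
    trsns = tm.gen_library(n_genes=500, n_trsns=40, n_pairs=5,
                           members_per_trsn=30, seed=2)
    return tm.assemble_matrix(tm.pair_and_merge(trsns))


def make_expression(treated: np.ndarray, control: np.ndarray,
                    genes: list[str] | None = None) -> tm.ExpressionMatrix:
    """Build an ExpressionMatrix from per-group value arrays (genes x samples)."""
    treated = np.atleast_2d(treated)
    control = np.atleast_2d(control)
    if genes is None:
        genes = [f"g{i}" for i in range(treated.shape[0])]
    values = pd.DataFrame(
        np.hstack([treated, control]), index=genes,
        columns=[f"t{i}" for i in range(treated.shape[1])]
        + [f"c{i}" for i in range(control.shape[1])],
    )
    group = pd.Series(
        [tm.diffexpr.TREATED] * treated.shape[1]
        + [tm.diffexpr.CONTROL] * control.shape[1],
        index=values.columns,
    )
    return tm.ExpressionMatrix(values=values, group=group)
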