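import numpy as np
import pandas as pd
import pytest

from batchscope.datamodel import BATCH_LEVELS, ExpressionMatrix, SampleSheet


def make_sheet(rows: list[dict]) -> SampleSheet:
    """Build a sample sheet from shorthand dicts (missing keys defaulted)."""
    full = []
    for i, r in enumerate(rows):
        d = {
            "sample_id": r.get("sample_id", f"s{i}"),
            "role": r.get("role", "biological"),
            "group": r.get("group"),
            "duplicate_id": r.get("duplicate_id"),
            "experiment": r.get("experiment", "E1"),
            "run": r.get("run", "E1.R1"),
            "chip": r.get("chip", "E1.R1.C1"),
            "array_position": r.get("array_position", f"A{i}"),
        }
        full.append(d)
    return SampleSheet(pd.DataFrame(full))


def nested_sheet(n_exp: int, n_run: int, n_chip: int, n_arr: int,
                 group_cycle: list[str] | None = None) -> SampleSheet:
    """Balanced nested sheet; groups (if given) interleave across arrays."""
    rows = []
    i = 0
    for e in range(n_exp):
        for r in range(n_run):
            for c in range(n_chip):
                for a in range(n_arr):
                    rows.append({
                        "sample_id": f"s{i}",
                        "experiment": f"E{e}",
                        "run": f"E{e}.R{r}",
                        "chip": f"E{e}.R{r}.C{c}",
                        "array_position": f"A{a}",
                        "group": group_cycle[i % len(group_cycle)]
                        if group_cycle else None,
                    })
                    i += 1
    return make_sheet(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]], index=["p1", "p2"], columns=["s1", "s2"]
    )
    return ExpressionMatrix(values)
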