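import numpy as np
import pandas as pd
import pytest

from foodlist import RunConfig, SimulationDesign, compress_bundle, gen_bundle

SMALL_DESIGN = SimulationDesign(
    n_participants=60, n_groups=6, types_per_group=2, brands_per_type=5,
    events_per_day_mean=3.0, n_supplement_codes=4, rng_seed=11)


@pytest.fixture(scope="session")
def small_bundle():
    """Moderate-heterogeneity bundle shared by read-only tests."""
    return gen_bundle(SMALL_DESIGN)


@pytest.fixture(scope="session")
def small_codemap(small_bundle):
    return compress_bundle(small_bundle)


@pytest.fixture(scope="session")
def sigma0_bundle():
    """Bundle whose brands are composition-identical within each food type."""
    design = SimulationDesign(
        n_participants=60, n_groups=6, types_per_group=2, brands_per_type=5,
        events_per_day_mean=3.0, n_supplement_codes=4,
        heterogeneity_sigma=0.0, rng_seed=11)
    return gen_bundle(design)


@pytest.fixture()
def config():
    return RunConfig()


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately loop-based and simple)


def kappa_oracle(a, b) -> float:
    a, b = list(a), list(b)
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    classes = set(a) | set(b)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in classes)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def average_ranks(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5


def tertile_oracle(values: pd.Series, n_classes: int = 3) -> pd.Series:
    items = sorted(zip(values.to_numpy(), values.index))
    n = len(items)
    base, rem = divmod(n, n_classes)
    labels = {}
    pos = 0
    for cls in range(1, n_classes + 1):
        size = base + (1 if cls <= rem else 0)
        for _, pid in items[pos:pos + size]:
            labels[pid] = cls
        pos += size
    return pd.Series([labels[i] for i in values.index], index=values.index)


def intake_oracle(events: pd.DataFrame, composition: pd.DataFrame,
                  participants: pd.DataFrame, recorded_days: int
                  ) -> pd.DataFrame:
    nutrients = [c for c in composition.columns if c != "code_id"]
    comp = {r["code_id"]: r for _, r in composition.iterrows()}
    totals = {pid: {n: 0.0 for n in nutrients}
              for pid in participants["participant_id"]}
    for _, ev in events.iterrows():
        row = comp[ev["code_id"]]
        for n in nutrients:
            totals[ev["participant_id"]][n] += ev["amount_g"] / 100.0 * row[n]
    out = pd.DataFrame(totals).T / recorded_days
    out.index.name = "participant_id"
    return out[nutrients].loc[participants["participant_id"]]


def cutpoint_oracle(intakes: pd.Series, thresholds: pd.Series,
                    retained: pd.Series, below: bool = True) -> float:
    """Percent of retained participants below (or above) their threshold."""
    num = den = 0
    for pid in intakes.index:
        if not retained.loc[pid] or np.isnan(thresholds.loc[pid]):
            continue
        den += 1
        if below and intakes.loc[pid] < thresholds.loc[pid]:
            num += 1
        if not below and intakes.loc[pid] > thresholds.loc[pid]:
            num += 1
    return 100.0 * num / den
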