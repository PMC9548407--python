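"""Data-driven construction of a reduced assessment battery.

Two complementary shortening steps:

* **test selection** — from a rotated factor solution, pick a small number
  of proxy tests per component: high loading on the target dimension, near
  zero on the others;
* **item halving** — for long tests, fit a single unrotated factor to the
  item-level correct/incorrect responses and keep the top half of items by
  loading, respecting any factorial design by analysing each design stratum
  separately.

The reduced battery is then rescored as percent correct over the retained
items only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ItemResponseMatrix",
    "ReductionSpec",
    "select_proxy_tests",
    "reduce_items",
    "score_reduced_battery",
]


@dataclass
class ItemResponseMatrix:
    """Patients × items binary responses for one test (NaN = missing)."""

    values: np.ndarray
    patient_ids: list[str]
    item_ids: list[str]
    test_name: str
    strata: list[list[int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ok = np.isnan(self.values) | (self.values == 0) | (self.values == 1)
        if not ok.all():
            raise ValueError("item responses must be 0, 1 or missing")
        if self.values.shape != (len(self.patient_ids), len(self.item_ids)):
            raise ValueError("shape mismatch")
        if self.strata is not None:
            flat = sorted(i for s in self.strata for i in s)
            if flat != list(range(len(self.item_ids))):
                raise ValueError("strata must partition the items")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def percent_scores(self, item_subset: list[int] | None = None) -> np.ndarray:
        """Percent correct per patient, exactly 100 × correct / n_items."""
        cols = np.arange(self.n_items) if item_subset is None else np.asarray(item_subset)
        sub = self.values[:, cols]
        return 100.0 * np.nansum(sub, axis=1) / sub.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.patient_ids, name="patient_id"),
                            columns=self.item_ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, na_rep="NA")


@dataclass
class ReductionSpec:
    """Configuration of the battery-reduction step.

    ``loading_floor`` / ``crossloading_ceiling`` operationalise "high on the
    target dimension and near zero elsewhere"; ``long_test_threshold`` is
    the item count above which a test is halved; ``priority`` optionally
    encodes clinical preference and breaks proxy ranking ties only.
    """

    proxies_per_component: int = 2
    long_test_threshold: int = 60
    retain_fraction: float = 0.5
    loading_floor: float = 0.5
    crossloading_ceiling: float = 0.3
    priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.retain_fraction <= 1):
            raise ValueError("retain_fraction must be in (0, 1]")
        if self.proxies_per_component < 1:
            raise ValueError("proxies_per_component must be >= 1")


# ---------------------------------------------------------------------------
# proxy-test selection
# ---------------------------------------------------------------------------


def select_proxy_tests(model, spec: ReductionSpec) -> dict[str, list[str]]:
    """Pick representative proxy tests per rotated component.

    A test is eligible for a component when its loading there is at least
    ``loading_floor`` and every off-target |loading| is at most
    ``crossloading_ceiling``.  Eligible tests are ranked by target loading
    (ties broken by the user priority list, then name) and the top
    ``proxies_per_component`` taken; a test is assigned to at most one
    component.
    """
    L = np.asarray(model.loadings)
    names = list(model.test_names)
    comps = list(model.component_names)
    prio = {name: i for i, name in enumerate(spec.priority)}

    chosen: dict[str, list[str]] = {}
    taken: set[str] = set()
    deficient: list[str] = []
    for c, comp in enumerate(comps):
        elig = []
        for j, test in enumerate(names):
            if test in taken:
                continue
            off = np.abs(np.delete(L[j], c))
            if L[j, c] >= spec.loading_floor and np.all(off <= spec.crossloading_ceiling):
                elig.append((-L[j, c], prio.get(test, len(prio)), test))
        elig.sort()
        if len(elig) < spec.proxies_per_component:
            deficient.append(comp)
            chosen[comp] = [e[2] for e in elig]
            continue
        picks = [e[2] for e in elig[: spec.proxies_per_component]]
        chosen[comp] = picks
        taken.update(picks)
    if deficient:
        raise ValueError(
            "not enough eligible proxy tests for component(s): " + ", ".join(deficient))
    return chosen


# ---------------------------------------------------------------------------
# item reduction
# ---------------------------------------------------------------------------


def _first_factor_loadings(x: np.ndarray) -> np.ndarray:
    """Unrotated first-principal-component loadings of item responses.

    Items are analysed on their Pearson correlations (raw 0/1 scores, not
    tetrachorics).  Zero-variance items receive loading 0.  The component
    sign is fixed so the summed loading is positive (i.e. the factor points
    toward "more items correct").
    """
    n, m = x.shape
    sd = np.nanstd(x, axis=0, ddof=1)
    live = sd > 0
    load = np.zeros(m)
    if live.sum() == 0:
        raise ValueError("all items have zero variance")
    xl = x[:, live]
    mu = np.nanmean(xl, axis=0)
    z = (xl - mu) / sd[live]
    z = np.where(np.isnan(z), 0.0, z)  # mean-impute missing responses
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    eig1 = s[0] ** 2 / (n - 1)
    l1 = vt[0] * np.sqrt(eig1)
    if l1.sum() < 0:
        l1 = -l1
    load[live] = l1
    return load


def reduce_items(items: ItemResponseMatrix, spec: ReductionSpec
                 ) -> tuple[list[str], pd.DataFrame]:
    """Retain the most informative fraction of items of one test.

    Within each design stratum (the whole test when none are declared) a
    single unrotated factor is fit to the items and the top
    ``ceil(retain_fraction × stratum size)`` items by loading retained.
    Ties are broken toward the lowest item index; zero-variance items get
    loading 0 and therefore lose ties.

    Returns the retained item ids plus a manifest table
    (item, stratum, loading, retained).
    """
    if items.n_items < 4:
        raise ValueError("need at least 4 items to reduce")
    strata = items.strata or [list(range(items.n_items))]
    loadings = np.zeros(items.n_items)
    stratum_of = np.zeros(items.n_items, dtype=int)
    retained_mask = np.zeros(items.n_items, dtype=bool)
    for s_idx, cell in enumerate(strata):
        cell = np.asarray(cell)
        stratum_of[cell] = s_idx
        l = _first_factor_loadings(items.values[:, cell])
        loadings[cell] = l
        n_keep = math.ceil(spec.retain_fraction * len(cell))
        # round so numerically identical items tie exactly, then a stable
        # sort on -loading keeps the lowest index first among ties
        order = np.argsort(-np.round(l, 10), kind="stable")
        retained_mask[cell[order[:n_keep]]] = True

    manifest = pd.DataFrame({
        "test": items.test_name,
        "stratum": stratum_of,
        "item_id": items.item_ids,
        "loading": loadings,
        "retained": retained_mask,
    })
    retained_ids = [items.item_ids[i] for i in range(items.n_items) if retained_mask[i]]
    return retained_ids, manifest


def score_reduced_battery(items_by_test: dict[str, ItemResponseMatrix],
                          retained: dict[str, list[str]],
                          proxy_map: dict[str, list[str]],
                          always_keep: list[str] | None = None):
    """Rescore the reduced battery as percent correct over retained items.

    Only the proxy tests (plus any ``always_keep`` short tests) appear as
    columns.  A test absent from ``retained`` keeps all its items.
    """
    from .dimension import ScoreMatrix  # local import avoids a cycle

    keep_tests: list[str] = []
    for tests in proxy_map.values():
        keep_tests.extend(tests)
    for t in always_keep or []:
        if t not in keep_tests:
            keep_tests.append(t)

    cols, ids = [], None
    for test in keep_tests:
        if test not in items_by_test:
            raise KeyError(f"no item responses for test {test}")
        irm = items_by_test[test]
        if ids is None:
            ids = list(irm.patient_ids)
        if test in retained:
            index = {iid: i for i, iid in enumerate(irm.item_ids)}
            try:
                subset = [index[iid] for iid in retained[test]]
            except KeyError as exc:
                raise KeyError(f"retained set of {test} references unknown item {exc}")
            if not subset:
                raise ValueError(f"retained set of {test} is empty")
            cols.append(irm.percent_scores(subset))
        else:
            cols.append(irm.percent_scores())
    return ScoreMatrix(np.column_stack(cols), ids, keep_tests)
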