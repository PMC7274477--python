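"""Shared resampling-null machinery for region-level enrichment tests.

Several figures-style analyses ask the same question: test regions show
some binary property (sitting in a super-enhancer with a TR-bound
region, sharing a TAD with one, ...) — is that more frequent than for
randomly drawn acetylated regions?  The null is one draw of ``n_random``
regions, sampled without replacement from the acetylated-region
universe with the test regions excluded, followed by a Fisher exact
test on the resulting 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import FisherResult, fisher_exact_2x2


@dataclass
class EnrichmentResult:
    observed_fraction: float
    random_fraction: float
    table: list = field(default_factory=list)  # [[a, b], [c, d]]
    odds_ratio: float = float("nan")
    p_value: float = 1.0
    n_test: int = 0
    n_random: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed_fraction": self.observed_fraction,
            "random_fraction": self.random_fraction,
            "table": self.table,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "n_test": self.n_test,
            "n_random": self.n_random,
            "seed": self.seed,
        }


def draw_random_regions(pool: pd.DataFrame, exclude_ids, n_random: int,
                        seed: int | None, id_col: str = "region_id") -> pd.DataFrame:
    """Sample ``n_random`` regions without replacement from pool minus excluded."""
    exclude = set(exclude_ids)
    avail = pool[~pool[id_col].isin(exclude)].reset_index(drop=True)
    if n_random > len(avail):
        raise ValueError(
            f"n_random={n_random} exceeds available pool size {len(avail)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(avail), size=n_random, replace=False)
    return avail.iloc[np.sort(idx)].reset_index(drop=True)


def enrichment_vs_random(test_positive: np.ndarray, random_positive: np.ndarray,
                         seed: int | None = None) -> EnrichmentResult:
    """Fisher test of {test, random} x {positive, negative}."""
    a = int(np.sum(test_positive))
    b = int(len(test_positive) - a)
    c = int(np.sum(random_positive))
    d = int(len(random_positive) - c)
    if len(test_positive) == 0:
        return EnrichmentResult(0.0, 0.0, [[0, 0], [c, d]], float("nan"), 1.0,
                                0, len(random_positive), seed)
    fr: FisherResult = fisher_exact_2x2([[a, b], [c, d]])
    return EnrichmentResult(
        observed_fraction=a / len(test_positive),
        random_fraction=c / len(random_positive) if len(random_positive) else float("nan"),
        table=[[a, b], [c, d]],
        odds_ratio=fr.odds_ratio,
        p_value=fr.p_value,
        n_test=len(test_positive),
        n_random=len(random_positive),
        seed=seed,
    )
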