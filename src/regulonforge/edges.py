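"""TF -> target-gene importance scoring with stochastic gradient boosting.

For every target gene a boosted regression ensemble predicts its normalized
expression from all TF expression columns (a TF never predicts itself); the
per-TF summed split gain is the edge importance, GRNBoost-style.  Edges below
the global 90th importance quantile are removed, and survivors are signed by
Pearson correlation: positive if r > 0.03, negative if r < -0.03 (strict);
anything in between is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor

from ._utils import DegenerateInputError, logger, pearson_columns

#: strict Pearson-correlation cutoff for edge signs
EDGE_SIGN_R = 0.03

#: fraction of the pooled importance distribution removed by the filter
IMPORTANCE_QUANTILE = 0.90


@dataclass
class EnsembleParams:
    """SGBM hyperparameters (GRNBoost-style defaults; configurable)."""

    n_estimators: int = 500
    learning_rate: float = 0.01
    subsample: float = 0.9
    num_leaves: int = 31
    min_child_samples: int = 10

    def make(self, seed: int) -> LGBMRegressor:
        return LGBMRegressor(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            subsample_freq=1,
            num_leaves=self.num_leaves,
            min_child_samples=self.min_child_samples,
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )


def compute_importances(
    expression: pd.DataFrame,
    tf_list: list[str],
    seed: int = 0,
    params: EnsembleParams | None = None,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Fit one boosted ensemble per target gene; return (tf, gene, importance).

    ``expression`` is cells x genes normalized expression containing every TF
    column; targets default to all genes.  Importances are summed split gains;
    constant targets yield all-zero importances (logged).  Deterministic for a
    fixed seed.
    """
    params = params or EnsembleParams()
    missing = [tf for tf in tf_list if tf not in expression.columns]
    if missing:
        raise DegenerateInputError(f"TFs absent from expression matrix: {missing}")
    targets = list(targets) if targets is not None else list(expression.columns)
    tf_arr = expression[tf_list].to_numpy(dtype=float)
    rows = []
    n_const = 0
    for gene in targets:
        y = expression[gene].to_numpy(dtype=float)
        predictors = [tf for tf in tf_list if tf != gene]
        if not predictors:
            continue
        if np.all(y == y[0]):
            n_const += 1
            for tf in predictors:
                rows.append({"tf": tf, "gene": gene, "importance": 0.0})
            continue
        cols = [tf_list.index(tf) for tf in predictors]
        model = params.make(seed)
        model.fit(tf_arr[:, cols], y)
        gains = model.booster_.feature_importance(importance_type="gain")
        for tf, gain in zip(predictors, gains):
            rows.append({"tf": tf, "gene": gene, "importance": float(gain)})
    if n_const:
        logger.warning("compute_importances: %d constant targets (zero importances)", n_const)
    return pd.DataFrame(rows, columns=["tf", "gene", "importance"])


def filter_importance_quantile(edges: pd.DataFrame, q: float = IMPORTANCE_QUANTILE) -> pd.DataFrame:
    """Keep rows with importance >= the q-th quantile (linear interpolation)
    of the pooled importance vector."""
    if not 0.0 < q < 1.0:
        raise DegenerateInputError("q must be in (0, 1)")
    if len(edges) == 0:
        return edges.copy()
    cut = np.quantile(edges["importance"].to_numpy(dtype=float), q)
    return edges[edges["importance"] >= cut].reset_index(drop=True)


def edge_sign(r: float) -> str | None:
    """Sign rule: strictly above 0.03 positive, strictly below -0.03 negative."""
    if np.isnan(r):
        return None
    if r > EDGE_SIGN_R:
        return "positive"
    if r < -EDGE_SIGN_R:
        return "negative"
    return None


def sign_edges(filtered: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Attach Pearson r and sign to importance-filtered edges.

    Pairs with |r| <= 0.03 or undefined correlation are dropped (constant
    columns logged).  Columns: tf, gene, importance, r, sign.
    """
    rows = []
    n_dropped_const = 0
    X = expression.to_numpy(dtype=float)
    pos = {c: i for i, c in enumerate(expression.columns)}
    for tf, sub in filtered.groupby("tf", sort=True):
        if tf not in pos:
            continue
        genes = [g for g in sub["gene"] if g in pos]
        if not genes:
            continue
        r_all = pearson_columns(X[:, pos[tf]], X[:, [pos[g] for g in genes]])
        imp = dict(zip(sub["gene"], sub["importance"]))
        for g, r in zip(genes, r_all):
            if np.isnan(r):
                n_dropped_const += 1
                continue
            sign = edge_sign(float(r))
            if sign is not None:
                rows.append({"tf": tf, "gene": g, "importance": imp[g],
                             "r": float(r), "sign": sign})
    if n_dropped_const:
        logger.warning("sign_edges: dropped %d pairs with undefined correlation",
                       n_dropped_const)
    return pd.DataFrame(rows, columns=["tf", "gene", "importance", "r", "sign"])
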