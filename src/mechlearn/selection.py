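"""Bootstrapped AICc model selection.

Candidate models fitted to the same surrogate draws are compared per draw
through their small-sample-corrected Akaike information criterion; each
draw's AICc differences are classified into an evidence trichotomy and the
class frequencies across draws form the selection matrix P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Evidence classes for Delta = AICc - min AICc within a draw.
E1_MAX = 3.0  # Delta <= 3: substantial evidence the model is among the best
E2_MAX = 8.0  # 3 < Delta <= 8: considerably less evidence
#               Delta > 8: essentially no evidence


def aicc(residuals: np.ndarray, a: int, d: int, r: int) -> float:
    """Small-sample corrected AIC from data residuals.

    ``residuals`` holds the differences between the PDE solution (sampled
    initial condition) and the replicate-averaged densities at every data
    coordinate; ``a + d + r`` counts the mechanism parameters, with one
    more for the noise variance.
    """
    residuals = np.asarray(residuals, float)
    nm = residuals.size
    k = a + d + r
    if nm <= k:
        raise ValueError(f"AICc undefined: {nm} residuals for {k} parameters")
    ssr = float(np.sum(residuals**2))
    aic = nm * np.log(ssr / nm) + 2.0 * (k + 1)
    return float(aic + 2.0 * (k + 1) * (k + 2) / (nm - k))


def classify_delta(delta: float) -> str:
    """Evidence class E1/E2/E3 of an AICc difference."""
    if delta < 0:
        raise ValueError("negative Delta: minimum subtraction bug upstream")
    if delta <= E1_MAX:
        return "E1"
    if delta <= E2_MAX:
        return "E2"
    return "E3"


@dataclass(frozen=True)
class SelectionMatrix:
    """3 x |M| matrix of evidence-class proportions.

    Row i gives P(E_i) per model; columns sum to 1, rows need not (several
    models can share the best-fitting class in the same draw).
    """

    p: np.ndarray
    models: list[str]
    B: int

    def __post_init__(self) -> None:
        if self.p.shape != (3, len(self.models)):
            raise ValueError("P must be 3 x |models|")
        if not np.allclose(self.p.sum(axis=0), 1.0, atol=1e-12):
            raise ValueError("columns of P must sum to 1")

    def best_model(self) -> str:
        """Model with the largest probability of the top evidence class."""
        return self.models[int(np.argmax(self.p[0]))]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.p, index=["P(E1)", "P(E2)", "P(E3)"], columns=self.models)


def selection_matrix(
    per_model_aicc: np.ndarray, models: list[str] | None = None
) -> SelectionMatrix:
    """Assemble P from an |M| x B array of per-draw AICc values.

    All models must share the same B draws (identical z per column).
    Columns containing NaN -- draws where any model failed -- are excluded
    for every model so the pairing stays intact.
    """
    A = np.asarray(per_model_aicc, float)
    if A.ndim != 2:
        raise ValueError("per_model_aicc must be |M| x B")
    n_models, B = A.shape
    if models is None:
        models = [f"model_{i + 1}" for i in range(n_models)]
    if len(models) != n_models:
        raise ValueError("model label count does not match AICc rows")
    keep = ~np.any(np.isnan(A), axis=0)
    if not keep.any():
        raise ValueError("no draw succeeded for every model")
    A = A[:, keep]
    delta = A - A.min(axis=0, keepdims=True)
    p = np.empty((3, n_models))
    p[0] = np.mean(delta <= E1_MAX, axis=1)
    p[1] = np.mean((delta > E1_MAX) & (delta <= E2_MAX), axis=1)
    p[2] = np.mean(delta > E2_MAX, axis=1)
    return SelectionMatrix(p, list(models), int(keep.sum()))
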