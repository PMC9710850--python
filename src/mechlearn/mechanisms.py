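"""Parametric mechanism library for the invasion PDE.

The governing model is

    du/dt = T(t; alpha) * [ d/dx( D(u; beta) du/dx ) + R(u; gamma) ],

with a multiplicative delay T in (0, 1] (post-scratch recovery), a
density-dependent diffusivity D (cell migration) and a reaction term R
(cell proliferation), all relative to a fixed carrying capacity K.  The
enumerated forms below cover the candidate models compared in the package:
no/logistic/probit/cloglog delay; constant (Fisher-Kolmogorov), porous
(Porous-Fisher), generalized Porous-FKPP and an extended two-power
diffusivity; logistic, Gompertz and Richards reactions.

Parameter values carried by these functions are in whatever unit system
the caller works in; :data:`PARAM_SPECS` records the conversion factors
between the rescaled fitting units (mm, d) and the raw reporting units
(um, h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr


class MechanismDomainError(ValueError):
    """Evaluation outside a form's mathematical domain."""


DELAY_FORMS = {"none": 0, "logistic": 2, "probit": 2, "cloglog": 2}
DIFFUSIVITY_FORMS = {"constant": 1, "porous": 1, "generalized": 3, "extended": 5}
REACTION_FORMS = {"logistic": 1, "gompertz": 1, "richards": 2}


@dataclass(frozen=True)
class ParamSpec:
    """Metadata for one mechanism parameter.

    ``to_raw`` converts a value in rescaled units (mm, d, density x 1e6)
    to the raw reporting units (um^2/h for diffusivities, h^-1 for rates).
    ``lo``/``hi`` bound the default Latin-hypercube starting box in
    rescaled units; ``log`` selects log-uniform sampling within the box.
    """

    name: str
    to_raw: float
    lo: float
    hi: float
    log: bool


_RATE = 1.0 / 24.0          # d^-1 -> h^-1
_DIFF = 1.0e6 / 24.0        # mm^2 d^-1 -> um^2 h^-1

_DELAY_SPECS = {
    "none": [],
    "logistic": [
        ParamSpec("alpha_1", 1.0, -5.0, 5.0, False),
        ParamSpec("alpha_2", _RATE, 0.1, 20.0, True),
    ],
}
_DELAY_SPECS["probit"] = _DELAY_SPECS["logistic"]
_DELAY_SPECS["cloglog"] = _DELAY_SPECS["logistic"]

_DIFF_SPECS = {
    "constant": [ParamSpec("beta_1", _DIFF, 1e-4, 1.0, True)],
    "porous": [ParamSpec("beta_2", _DIFF, 1e-4, 1.0, True)],
    "generalized": [
        ParamSpec("beta_1", _DIFF, 1e-4, 1.0, True),
        ParamSpec("beta_2", _DIFF, 1e-4, 1.0, True),
        ParamSpec("beta_3", 1.0, 0.5, 5.0, False),
    ],
    "extended": [
        ParamSpec("beta_1", _DIFF, 1e-4, 1.0, True),
        ParamSpec("beta_2", _DIFF, 1e-4, 1.0, True),
        ParamSpec("beta_3", 1.0, 0.5, 5.0, False),
        ParamSpec("beta_4", _DIFF, 1e-4, 1.0, True),
        ParamSpec("beta_5", 1.0, 0.5, 5.0, False),
    ],
}

_REACTION_SPECS = {
    "logistic": [ParamSpec("gamma_1", _RATE, 0.1, 10.0, True)],
    "gompertz": [ParamSpec("gamma_1", _RATE, 0.1, 10.0, True)],
    "richards": [
        ParamSpec("gamma_1", _RATE, 0.1, 10.0, True),
        ParamSpec("gamma_2", 1.0, 0.2, 5.0, False),
    ],
}


def evaluate_delay(form: str, alpha, t):
    """Delay factor T(t; alpha) in (0, 1]."""
    alpha = np.asarray(alpha, float)
    expected = DELAY_FORMS.get(form)
    if expected is None:
        raise MechanismDomainError(f"unknown delay form {form!r}")
    if alpha.size != expected:
        raise MechanismDomainError(
            f"delay form {form!r} needs {expected} parameter(s), got {alpha.size}"
        )
    t = np.asarray(t, float)
    if form == "none":
        return np.ones_like(t)
    eta = alpha[0] + alpha[1] * t
    if form == "logistic":
        return expit(eta)
    if form == "probit":
        return ndtr(eta)
    # complementary log-log
    with np.errstate(over="ignore"):
        return 1.0 - np.exp(-np.exp(eta))


def evaluate_diffusivity(form: str, beta, u, K: float):
    """Diffusivity D(u; beta) and its analytic derivative dD/du.

    No positivity clamping is applied here: negative D values are the
    responsibility of the physical-feasibility barrier in the loss.
    Fractional powers of negative densities are a domain error.
    """
    beta = np.asarray(beta, float)
    expected = DIFFUSIVITY_FORMS.get(form)
    if expected is None:
        raise MechanismDomainError(f"unknown diffusivity form {form!r}")
    if beta.size != expected:
        raise MechanismDomainError(
            f"diffusivity form {form!r} needs {expected} parameter(s), got {beta.size}"
        )
    u = np.asarray(u, float)
    if form == "constant":
        return beta[0] * np.ones_like(u), np.zeros_like(u)
    frac = u / K
    if form == "porous":
        return beta[0] * frac, np.full_like(u, beta[0] / K)
    if form == "generalized":
        p = _power(frac, beta[2])
        dp = _power_derivative(frac, beta[2]) / K
        return beta[0] + beta[1] * p, beta[1] * dp
    # extended: two power terms
    p1 = _power(frac, beta[2])
    p2 = _power(frac, beta[4])
    dp1 = _power_derivative(frac, beta[2]) / K
    dp2 = _power_derivative(frac, beta[4]) / K
    return beta[0] + beta[1] * p1 + beta[3] * p2, beta[1] * dp1 + beta[3] * dp2


def _power(frac: np.ndarray, expo: float) -> np.ndarray:
    if np.any(frac < 0) and expo != np.round(expo):
        raise MechanismDomainError("fractional power of a negative density")
    if np.any(frac == 0) and expo <= 0:
        raise MechanismDomainError("non-positive exponent at zero density")
    with np.errstate(invalid="ignore"):
        return np.power(frac, expo)


def _power_derivative(frac: np.ndarray, expo: float) -> np.ndarray:
    # d/dfrac frac**expo = expo * frac**(expo-1); at frac == 0 the limit is
    # 0 for expo > 1, expo for expo == 1, and +inf below (surfaces as an
    # infinite loss downstream).
    out = np.empty_like(frac)
    zero = frac == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[~zero] = expo * np.power(frac[~zero], expo - 1.0)
    if np.any(zero):
        if expo > 1:
            out[zero] = 0.0
        elif expo == 1:
            out[zero] = 1.0
        else:
            out[zero] = np.inf
    return out


def evaluate_reaction(form: str, gamma, u, K: float):
    """Reaction (proliferation) term R(u; gamma); R(K) = 0 for all forms."""
    gamma = np.asarray(gamma, float)
    expected = REACTION_FORMS.get(form)
    if expected is None:
        raise MechanismDomainError(f"unknown reaction form {form!r}")
    if gamma.size != expected:
        raise MechanismDomainError(
            f"reaction form {form!r} needs {expected} parameter(s), got {gamma.size}"
        )
    u = np.asarray(u, float)
    if form == "logistic":
        return gamma[0] * u * (1.0 - u / K)
    if form == "gompertz":
        if np.any(u < 0):
            raise MechanismDomainError("Gompertz reaction undefined for u < 0")
        # u log(K/u) -> 0 as u -> 0+
        out = np.zeros_like(u)
        pos = u > 0
        out[pos] = gamma[0] * u[pos] * np.log(K / u[pos])
        return out
    # richards
    return gamma[0] * u * (1.0 - _power(u / K, gamma[1]))


@dataclass(frozen=True)
class MechanismModel:
    """A (T, D, R) candidate model with carrying capacity K.

    ``K`` must be supplied in the unit system the model is evaluated in
    (the rescaled density scale during fitting).
    """

    delay_form: str
    diffusivity_form: str
    reaction_form: str = "logistic"
    K: float = 1.7e-3
    label: str = ""

    def __post_init__(self) -> None:
        if self.delay_form not in DELAY_FORMS:
            raise MechanismDomainError(f"unknown delay form {self.delay_form!r}")
        if self.diffusivity_form not in DIFFUSIVITY_FORMS:
            raise MechanismDomainError(
                f"unknown diffusivity form {self.diffusivity_form!r}"
            )
        if self.reaction_form not in REACTION_FORMS:
            raise MechanismDomainError(f"unknown reaction form {self.reaction_form!r}")
        if self.K <= 0:
            raise MechanismDomainError("carrying capacity K must be positive")

    @property
    def a(self) -> int:
        return DELAY_FORMS[self.delay_form]

    @property
    def d(self) -> int:
        return DIFFUSIVITY_FORMS[self.diffusivity_form]

    @property
    def r(self) -> int:
        return REACTION_FORMS[self.reaction_form]

    @property
    def n_params(self) -> int:
        return self.a + self.d + self.r

    @property
    def param_specs(self) -> list[ParamSpec]:
        return (
            list(_DELAY_SPECS[self.delay_form])
            + list(_DIFF_SPECS[self.diffusivity_form])
            + list(_REACTION_SPECS[self.reaction_form])
        )

    @property
    def param_names(self) -> list[str]:
        return [s.name for s in self.param_specs]

    def split(self, theta) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Split a stacked parameter vector into (alpha, beta, gamma)."""
        theta = np.asarray(theta, float)
        if theta.size != self.n_params:
            raise MechanismDomainError(
                f"model expects {self.n_params} parameters, got {theta.size}"
            )
        a, d = self.a, self.d
        return theta[:a], theta[a : a + d], theta[a + d :]

    def delay(self, theta, t):
        alpha, _, _ = self.split(theta)
        return evaluate_delay(self.delay_form, alpha, t)

    def diffusivity(self, theta, u):
        _, beta, _ = self.split(theta)
        return evaluate_diffusivity(self.diffusivity_form, beta, u, self.K)

    def reaction(self, theta, u):
        _, _, gamma = self.split(theta)
        return evaluate_reaction(self.reaction_form, gamma, u, self.K)

    def with_K(self, K: float) -> "MechanismModel":
        return MechanismModel(
            self.delay_form, self.diffusivity_form, self.reaction_form, K, self.label
        )


def model_catalog(K: float = 1.7e-3) -> list[MechanismModel]:
    """The five standard candidate models (all with logistic reaction).

    1. Fisher-Kolmogorov (no delay, constant D)
    2. delayed Fisher-Kolmogorov
    3. Porous-Fisher (no delay, D linear in u)
    4. delayed Porous-Fisher
    5. delayed generalized Porous-FKPP (D = beta_1 + beta_2 (u/K)^beta_3)

    The five-parameter extended diffusivity is available through
    :class:`MechanismModel` but excluded here: with this little data its
    extra powers are weakly identifiable.
    """
    combos = [
        ("none", "constant", "Model 1"),
        ("logistic", "constant", "Model 2"),
        ("none", "porous", "Model 3"),
        ("logistic", "porous", "Model 4"),
        ("logistic", "generalized", "Model 5"),
    ]
    return [
        MechanismModel(delay, diff, "logistic", K, label)
        for delay, diff, label in combos
    ]
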