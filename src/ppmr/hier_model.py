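"""Bayesian nested linear mixed model for group-level PPMR.

Model
-----
For group g (a species x 0.1-log10-mass-bin x subregion cell),

    log10 R_g = b0 + b1*x_g + b2*x2_g
                + sum over levels l of (u_{l,0} + u_{l,1}*x_g + u_{l,2}*x2_g)
                + eps_g,        eps_g ~ N(0, sigma^2)

where x is the centered/scaled log10 weighted mean predator mass and x2 the
independently centered/scaled *square* of log10 mass (not the square of the
scaled predictor).  The random-effect levels are nested: subregion within
region, region within species, species within family, family within order;
each level carries its own uncorrelated intercept / linear / quadratic
deviations with level-specific standard deviations.

Priors: fixed effects Normal(0, variance 3); random-effect sds
half-Cauchy(0, 10); residual sd half-Student-t (df 3, scale 10) by default,
or InverseGamma(0.001, 0.001) on the variance under ``prior_residual=
"literal"``.

Sampler
-------
A blocked Gibbs sampler exploits full conditional conjugacy: the
half-Cauchy and half-t sd priors are written as inverse-gamma scale
mixtures (parameter expansion), after which every update is a draw from a
normal or inverse-gamma full conditional.  Coefficient blocks are sampled
jointly per grouping unit (3x3 solves, batched).  Convergence is checked
with split-R-hat across chains (fit rejected when max R-hat >= 1.2).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import arviz as az
import numpy as np
import pandas as pd

from .errors import (
    InvalidDesignError,
    InvalidResponseError,
    NoConvergenceError,
    UnknownGroupError,
)

LEVELS = ("order", "family", "species", "region", "subregion")
TERMS = ("intercept", "linear", "quadratic")

#: prior scale settings
FIXED_PRIOR_VAR = 3.0
SD_CAUCHY_SCALE = 10.0
RESID_T_DF = 3.0
RESID_T_SCALE = 10.0
RESID_LITERAL_SHAPE = 0.001
RESID_LITERAL_RATE = 0.001
RHAT_MAX = 1.2


@dataclass
class McmcSettings:
    chains: int = 3
    iterations: int = 1000
    burn_in: int = 300
    thin: int = 1

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: "paper-mcmc" mirrors the original study's chain settings; the default
#: uses a 4x longer adaptation period and no thinning.
PRESETS = {
    "default": McmcSettings(chains=3, iterations=1000, burn_in=300, thin=1),
    "paper-mcmc": McmcSettings(chains=3, iterations=1550, burn_in=50, thin=3),
}


@dataclass
class PredictorScaler:
    """Independent standardisation of log10 mass and its square."""

    mean_x: float
    sd_x: float
    mean_x2: float
    sd_x2: float

    def transform(self, log10_mass):
        u = np.asarray(log10_mass, dtype=float)
        return (u - self.mean_x) / self.sd_x, (u ** 2 - self.mean_x2) / self.sd_x2

    def raw_coefs(self, beta):
        """Convert scaled-basis coefficients to the raw polynomial basis.

        beta has shape (..., 3); returns coefficients (A0, A1, A2) of
        A0 + A1*u + A2*u^2 with u = log10 mass.
        """
        b = np.asarray(beta, dtype=float)
        a2 = b[..., 2] / self.sd_x2
        a1 = b[..., 1] / self.sd_x
        a0 = (b[..., 0] - b[..., 1] * self.mean_x / self.sd_x
              - b[..., 2] * self.mean_x2 / self.sd_x2)
        return np.stack([a0, a1, a2], axis=-1)


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray                       # (n, 3): [1, x, x2]
    codes: dict                         # level -> (n,) int array
    labels: dict                        # level -> list of nested label tuples
    scaler: PredictorScaler
    response: str
    log10_mass: np.ndarray
    groups: pd.DataFrame                # canonical-sorted source table

    @property
    def n(self) -> int:
        return self.y.size


def build_design(groups: pd.DataFrame, response: str = "R_bio") -> Design:
    """Build the model design from a group-level PPMR table.

    The mass predictor is matched to the response weighting (count-weighted
    mean mass for R_num, specific-prey-mass-weighted for R_bio).  Rows are
    canonically sorted so the design is invariant to input row order.
    """
    if response not in ("R_bio", "R_num"):
        raise InvalidResponseError(f"unknown response {response!r}")
    mass_col = "mean_mass_biow_g" if response == "R_bio" else "mean_mass_numw_g"
    df = groups.sort_values(
        ["order", "family", "species", "region", "subregion", "bin_lo_log10g"],
        kind="mergesort",
    ).reset_index(drop=True)

    r = df[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise InvalidResponseError("response must be positive and finite")
    mass = df[mass_col].to_numpy(dtype=float)
    if np.any(mass <= 0):
        raise InvalidResponseError("mean predator mass must be positive")
    u = np.log10(mass)
    if np.unique(u).size < 2:
        raise InvalidDesignError("need at least 2 distinct predator masses")

    scaler = PredictorScaler(
        mean_x=float(u.mean()), sd_x=float(u.std(ddof=1)),
        mean_x2=float((u ** 2).mean()), sd_x2=float((u ** 2).std(ddof=1)),
    )
    x, x2 = scaler.transform(u)
    X = np.column_stack([np.ones_like(x), x, x2])

    codes, labels = {}, {}
    path_cols = {
        "order": ["order"],
        "family": ["order", "family"],
        "species": ["order", "family", "species"],
        "region": ["order", "family", "species", "region"],
        "subregion": ["order", "family", "species", "region", "subregion"],
    }
    for level in LEVELS:
        paths = list(map(tuple, df[path_cols[level]].itertuples(index=False)))
        uniq = sorted(set(paths))
        index = {p: i for i, p in enumerate(uniq)}
        codes[level] = np.asarray([index[p] for p in paths], dtype=np.intp)
        labels[level] = uniq
    return Design(
        y=np.log10(r), X=X, codes=codes, labels=labels, scaler=scaler,
        response=response, log10_mass=u, groups=df,
    )


def _unit_grams(X: np.ndarray, codes: np.ndarray, n_units: int) -> np.ndarray:
    """Per-unit Gram matrices sum_i X_i X_i' as an (n_units, 3, 3) array."""
    G = np.empty((n_units, 3, 3))
    for j in range(3):
        for k in range(j, 3):
            s = np.bincount(codes, weights=X[:, j] * X[:, k], minlength=n_units)
            G[:, j, k] = s
            G[:, k, j] = s
    return G


def _unit_xtr(X, codes, r, n_units):
    out = np.empty((n_units, 3))
    for j in range(3):
        out[:, j] = np.bincount(codes, weights=X[:, j] * r, minlength=n_units)
    return out


def _sample_mvn_blocks(prec: np.ndarray, xtr_over_s2: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^{-1} m, prec^{-1}) for a batch of 3x3 blocks."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, xtr_over_s2[..., None])[..., 0]
    z = rng.standard_normal(mean.shape)
    Lt = np.swapaxes(L, -1, -2)
    return mean + np.linalg.solve(Lt, z[..., None])[..., 0]


def _parent_maps(design: Design) -> dict:
    """child level -> (parent level, child-unit -> parent-unit index array)."""
    maps = {}
    for child, parent in zip(LEVELS[1:], LEVELS[:-1]):
        pindex = {p: i for i, p in enumerate(design.labels[parent])}
        depth = len(design.labels[parent][0])
        maps[child] = (
            parent,
            np.asarray(
                [pindex[lab[:depth]] for lab in design.labels[child]],
                dtype=np.intp,
            ),
        )
    return maps


def _sweep(beta, b, sd2, parent_maps, rng):
    """Translation-group moves between nested levels (generalized Gibbs).

    For each (child, parent) pair and each term, shift the child
    deviations of every parent unit by a common constant absorbed into the
    parent coefficient.  The linear predictor is invariant (each
    observation sits in exactly one child of exactly one parent), so the
    conditional for the shift is Gaussian in the priors alone.  These moves
    decouple the otherwise near-unidentified fixed intercept from the sums
    of random intercepts and restore fast mixing.
    """
    for child in reversed(LEVELS[1:]):
        parent, pmap = parent_maps[child]
        n_par = b[parent].shape[0]
        counts = np.bincount(pmap, minlength=n_par).astype(float)
        for k in range(3):
            child_sums = np.bincount(pmap, weights=b[child][:, k], minlength=n_par)
            prec = 1.0 / sd2[parent][k] + counts / sd2[child][k]
            mean = (-b[parent][:, k] / sd2[parent][k]
                    + child_sums / sd2[child][k]) / prec
            c = mean + rng.standard_normal(n_par) / np.sqrt(prec)
            b[child][:, k] -= c[pmap]
            b[parent][:, k] += c
    # top level vs fixed effects
    top = LEVELS[0]
    n_top = b[top].shape[0]
    for k in range(3):
        prec = 1.0 / FIXED_PRIOR_VAR + n_top / sd2[top][k]
        mean = (-beta[k] / FIXED_PRIOR_VAR
                + b[top][:, k].sum() / sd2[top][k]) / prec
        c = mean + rng.standard_normal() / math.sqrt(prec)
        b[top][:, k] -= c
        beta[k] += c
    return beta


def _slice_sample(x0: float, logf, rng, w: float, max_steps: int = 50) -> float:
    """Univariate slice sampler (stepping out + shrinkage)."""
    logy = logf(x0) + math.log(rng.random() + 1e-300)
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logf(lo) < logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) < logy:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _run_chain(design: Design, settings: McmcSettings, prior_residual: str, rng):
    y, X = design.y, design.X
    n = y.size
    n_units = {l: len(design.labels[l]) for l in LEVELS}
    grams = {l: _unit_grams(X, design.codes[l], n_units[l]) for l in LEVELS}
    parent_maps = _parent_maps(design)

    # state
    XtX = X.T @ X
    beta = np.linalg.solve(XtX + np.eye(3) / FIXED_PRIOR_VAR, X.T @ y)
    b = {l: np.zeros((n_units[l], 3)) for l in LEVELS}
    contrib = {l: np.zeros(n) for l in LEVELS}
    sd2 = {l: np.full(3, 0.25) for l in LEVELS}
    aux = {l: np.ones(3) for l in LEVELS}
    resid0 = y - X @ beta
    sigma2 = max(float(resid0 @ resid0) / max(n - 3, 1), 1e-6)
    aux_res = 1.0

    n_keep = settings.draws_per_chain
    out_beta = np.empty((n_keep, 3))
    out_b = {l: np.empty((n_keep, n_units[l], 3)) for l in LEVELS}
    out_sd = {l: np.empty((n_keep, 3)) for l in LEVELS}
    out_sigma = np.empty(n_keep)
    kept = 0

    eye3 = np.eye(3)
    for it in range(settings.iterations):
        total_re = sum(contrib.values())
        # fixed effects
        r = y - total_re
        prec = XtX / sigma2 + eye3 / FIXED_PRIOR_VAR
        beta = _sample_mvn_blocks(prec[None], (X.T @ r / sigma2)[None], rng)[0]
        fixed_part = X @ beta

        # random-effect blocks, level by level
        for level in LEVELS:
            r = y - fixed_part - (total_re - contrib[level])
            xtr = _unit_xtr(X, design.codes[level], r, n_units[level])
            prec = grams[level] / sigma2 + np.diag(1.0 / sd2[level])[None]
            b[level] = _sample_mvn_blocks(prec, xtr / sigma2, rng)
            contrib[level] = np.einsum(
                "ij,ij->i", X, b[level][design.codes[level]]
            )
            total_re = sum(contrib.values())

        beta = _sweep(beta, b, sd2, parent_maps, rng)
        fixed_part = X @ beta
        for level in LEVELS:
            contrib[level] = np.einsum(
                "ij,ij->i", X, b[level][design.codes[level]]
            )
        total_re = sum(contrib.values())

        # level sds: half-Cauchy(0, 10) via inverse-gamma scale mixture
        for level in LEVELS:
            ss = np.sum(b[level] ** 2, axis=0)
            shape = 0.5 * (1.0 + n_units[level])
            rate = 1.0 / aux[level] + 0.5 * ss
            sd2[level] = rate / rng.gamma(shape, 1.0, size=3)
            aux[level] = (1.0 / sd2[level] + SD_CAUCHY_SCALE ** -2) / rng.gamma(
                1.0, 1.0, size=3
            )

        # interweaved (non-centered) sd update: holding the standardised
        # deviations fixed, the signed sd enters the likelihood linearly,
        # so its conditional is Gaussian-likelihood x Cauchy-prior; a slice
        # step samples it.  This breaks the funnel stickiness of
        # near-zero variance components.
        resid_full = y - fixed_part - total_re
        for level in LEVELS:
            codes_l = design.codes[level]
            for k in range(3):
                s_old = math.sqrt(sd2[level][k])
                if s_old < 1e-12:
                    continue
                c = b[level][codes_l, k] * X[:, k]
                g = c / s_old
                gg = float(g @ g)
                if gg < 1e-14:
                    continue
                r = resid_full + c
                gr = float(g @ r)
                prec_lik = gg / sigma2
                mean_lik = gr / gg

                def logf(s, _p=prec_lik, _m=mean_lik):
                    return (-0.5 * _p * (s - _m) ** 2
                            - math.log1p((s / SD_CAUCHY_SCALE) ** 2))

                s_new = _slice_sample(
                    s_old, logf, rng, w=1.0 / math.sqrt(prec_lik) + 0.05
                )
                ratio = s_new / s_old
                b[level][:, k] *= ratio
                sd2[level][k] = s_new * s_new
                delta = (ratio - 1.0) * c
                contrib[level] = contrib[level] + delta
                total_re = total_re + delta
                resid_full = resid_full - delta
                # refresh the scale-mixture auxiliary for the new sd
                aux[level][k] = (
                    1.0 / sd2[level][k] + SD_CAUCHY_SCALE ** -2
                ) / rng.gamma(1.0, 1.0)

        # residual variance
        resid = y - fixed_part - total_re
        sse = float(resid @ resid)
        if prior_residual == "literal":
            shape = RESID_LITERAL_SHAPE + 0.5 * n
            rate = RESID_LITERAL_RATE + 0.5 * sse
        else:
            shape = 0.5 * (RESID_T_DF + n)
            rate = RESID_T_DF / aux_res + 0.5 * sse
        sigma2 = rate / rng.gamma(shape, 1.0)
        if prior_residual != "literal":
            aux_res = (RESID_T_DF / sigma2 + RESID_T_SCALE ** -2) / rng.gamma(
                0.5 * (RESID_T_DF + 1.0), 1.0
            )

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            if kept < n_keep:
                out_beta[kept] = beta
                for level in LEVELS:
                    out_b[level][kept] = b[level]
                    out_sd[level][kept] = np.sqrt(sd2[level])
                out_sigma[kept] = np.sqrt(sigma2)
                kept += 1
    return out_beta, out_b, out_sd, out_sigma


@dataclass
class PosteriorFit:
    """Posterior draws and metadata for one fitted response."""

    response: str
    beta: np.ndarray                    # (S, 3)
    b: dict                             # level -> (S, n_units, 3)
    sd: dict                            # level -> (S, 3)
    sigma: np.ndarray                   # (S,)
    scaler: PredictorScaler
    labels: dict                        # level -> list of nested label tuples
    chains: int
    diagnostics: dict = field(default_factory=dict)
    mass_range_log10: tuple = (0.0, 0.0)
    settings: McmcSettings | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    # -- label resolution ---------------------------------------------------

    def _index(self, level: str) -> dict:
        return {p: i for i, p in enumerate(self.labels[level])}

    def species_taxonomy(self) -> dict:
        """Map species name -> (order, family) from the training labels."""
        return {p[2]: (p[0], p[1]) for p in self.labels["species"]}

    def resolve_path(self, level: str, species=None, family=None, order=None,
                     region=None, subregion=None):
        """Return the unit index path for ``level``, or raise UnknownGroupError."""
        if level == "fixed":
            return None
        taxo = self.species_taxonomy()
        if species is not None and species in taxo:
            order, family = taxo[species]
        if level == "order":
            path = (order,)
        elif level == "family":
            path = (order, family)
        elif level == "species":
            path = (order, family, species)
        elif level == "region":
            path = (order, family, species, region)
        elif level == "subregion":
            path = (order, family, species, region, subregion)
        else:
            raise UnknownGroupError(f"unknown level {level!r}")
        idx = self._index(level).get(path)
        if idx is None:
            raise UnknownGroupError(f"{level} labels {path} not in training data")
        return idx

    def has_group(self, level: str, **labels) -> bool:
        try:
            self.resolve_path(level, **labels)
            return True
        except UnknownGroupError:
            return False

    # -- prediction ---------------------------------------------------------

    def predict_R(self, species=None, region=None, subregion=None,
                  mass_bin_lo: float | None = None, level: str = "subregion",
                  family=None, order=None, mass_log10: float | None = None,
                  bias_correct: bool = False) -> np.ndarray:
        """Posterior draws of R (ratio scale) for one group at one mass.

        The mass predictor is the bin midpoint (``mass_bin_lo + 0.05`` in
        log10 g) unless ``mass_log10`` is given.  ``level`` selects how deep
        in the nesting random effects are included ("fixed" for none).
        Predictions outside the trained mass range are allowed but warned
        about.
        """
        if mass_log10 is None:
            if mass_bin_lo is None:
                raise ValueError("need mass_bin_lo or mass_log10")
            mass_log10 = mass_bin_lo + 0.05
        lo, hi = self.mass_range_log10
        if not lo <= mass_log10 <= hi:
            warnings.warn(
                f"predicting at log10 mass {mass_log10:.2f} outside the "
                f"trained range [{lo:.2f}, {hi:.2f}]",
                stacklevel=2,
            )
        x, x2 = self.scaler.transform(mass_log10)
        xvec = np.array([1.0, float(x), float(x2)])
        eta = self.beta @ xvec
        if level != "fixed":
            depth = LEVELS.index(level)
            for l in LEVELS[: depth + 1]:
                idx = self.resolve_path(
                    l, species=species, family=family, order=order,
                    region=region, subregion=subregion,
                )
                eta = eta + self.b[l][:, idx, :] @ xvec
        if bias_correct:
            eta = eta + 0.5 * self.sigma ** 2 * np.log(10.0)
        return 10.0 ** eta

    def fixed_draws_raw(self) -> np.ndarray:
        """Fixed-effect draws on the raw log10-mass polynomial basis."""
        return self.scaler.raw_coefs(self.beta)

    # -- persistence --------------------------------------------------------

    def to_dir(self, path) -> None:
        from pathlib import Path

        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        rows = []
        S = self.n_draws
        for s in range(S):
            rows.append((s, "sigma", self.sigma[s]))
            for j, t in enumerate(TERMS):
                rows.append((s, f"beta[{t}]", self.beta[s, j]))
            for level in LEVELS:
                for j, t in enumerate(TERMS):
                    rows.append((s, f"sd[{level},{t}]", self.sd[level][s, j]))
                for ui, lab in enumerate(self.labels[level]):
                    for j, t in enumerate(TERMS):
                        rows.append(
                            (s, f"b[{level},{'/'.join(lab)},{t}]",
                             self.b[level][s, ui, j])
                        )
        pd.DataFrame(rows, columns=["draw", "parameter", "value"]).to_csv(
            d / "draws.csv", index=False
        )
        meta = {
            "response": self.response,
            "chains": self.chains,
            "scaler": asdict(self.scaler),
            "labels": {l: [list(p) for p in self.labels[l]] for l in LEVELS},
            "diagnostics": self.diagnostics,
            "mass_range_log10": list(self.mass_range_log10),
            "settings": asdict(self.settings) if self.settings else None,
        }
        (d / "fit.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_dir(cls, path) -> "PosteriorFit":
        from pathlib import Path

        d = Path(path)
        meta = json.loads((d / "fit.json").read_text())
        labels = {l: [tuple(p) for p in meta["labels"][l]] for l in LEVELS}
        draws = pd.read_csv(d / "draws.csv")
        S = int(draws["draw"].max()) + 1
        wide = draws.pivot(index="draw", columns="parameter", values="value")
        beta = np.column_stack([wide[f"beta[{t}]"] for t in TERMS])
        sigma = wide["sigma"].to_numpy()
        b, sd = {}, {}
        for level in LEVELS:
            sd[level] = np.column_stack(
                [wide[f"sd[{level},{t}]"] for t in TERMS]
            )
            arr = np.empty((S, len(labels[level]), 3))
            for ui, lab in enumerate(labels[level]):
                for j, t in enumerate(TERMS):
                    arr[:, ui, j] = wide[f"b[{level},{'/'.join(lab)},{t}]"]
            b[level] = arr
        settings = McmcSettings(**meta["settings"]) if meta["settings"] else None
        return cls(
            response=meta["response"], beta=beta, b=b, sd=sd, sigma=sigma,
            scaler=PredictorScaler(**meta["scaler"]), labels=labels,
            chains=meta["chains"], diagnostics=meta["diagnostics"],
            mass_range_log10=tuple(meta["mass_range_log10"]),
            settings=settings,
        )


def fit(design: Design, settings: McmcSettings | str = "default",
        seed: int = 0, prior_residual: str = "half-t",
        rhat_max: float = RHAT_MAX, check_convergence: bool = True
        ) -> PosteriorFit:
    """Run the Gibbs sampler and return an accepted posterior fit.

    ``settings`` may be a preset name ("default", "paper-mcmc") or explicit
    :class:`McmcSettings`.  All chains derive their streams from ``seed``
    deterministically.  The fit is rejected with
    :class:`NoConvergenceError` when max split-R-hat >= ``rhat_max``.
    """
    if isinstance(settings, str):
        settings = PRESETS[settings]
    if design.n < 2:
        raise InvalidDesignError("need at least two groups to fit")
    n_keep = settings.draws_per_chain
    if n_keep * settings.chains < 500:
        raise InvalidDesignError(
            "settings yield fewer than 500 posterior draws"
        )
    ss = np.random.SeedSequence(seed)
    chains = []
    for child in ss.spawn(settings.chains):
        rng = np.random.default_rng(child)
        chains.append(_run_chain(design, settings, prior_residual, rng))

    c_beta = np.stack([c[0] for c in chains])              # (C, S, 3)
    c_sigma = np.stack([c[3] for c in chains])             # (C, S)
    c_sd = {l: np.stack([c[2][l] for c in chains]) for l in LEVELS}
    posterior = {"beta": c_beta, "sigma": c_sigma}
    for l in LEVELS:
        posterior[f"sd_{l}"] = c_sd[l]
    idata = az.from_dict(posterior=posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    diagnostics = {
        "rhat": {v: np.atleast_1d(rhat[v].values).tolist() for v in rhat.data_vars},
        "ess": {v: np.atleast_1d(ess[v].values).tolist() for v in ess.data_vars},
    }
    max_rhat = max(
        float(np.nanmax(np.atleast_1d(rhat[v].values))) for v in rhat.data_vars
    )
    diagnostics["max_rhat"] = max_rhat
    if check_convergence and not max_rhat < rhat_max:
        raise NoConvergenceError(
            f"max split-R-hat {max_rhat:.3f} >= {rhat_max}",
            diagnostics=diagnostics,
        )

    S = n_keep * settings.chains
    result = PosteriorFit(
        response=design.response,
        beta=c_beta.reshape(S, 3),
        b={l: np.concatenate([c[1][l] for c in chains]) for l in LEVELS},
        sd={l: c_sd[l].reshape(S, 3) for l in LEVELS},
        sigma=c_sigma.reshape(S),
        scaler=design.scaler,
        labels=design.labels,
        chains=settings.chains,
        diagnostics=diagnostics,
        mass_range_log10=(float(design.log10_mass.min()),
                          float(design.log10_mass.max())),
        settings=settings,
    )
    return result


def hpd(draws, prob: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval of a 1-D draw vector."""
    arr = np.asarray(draws, dtype=float).ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo, hi = az.hdi(arr, hdi_prob=prob)
    return float(lo), float(hi)


#: the fixed ordering of level sets in the sequential R-squared report
R2_LEVEL_SETS = ("fixed", "+order", "+family", "+species", "+region", "+subregion")


def bayesian_r2_sequence(fit_result: PosteriorFit, design: Design,
                         prob: float = 0.95) -> pd.DataFrame:
    """Sequential Bayesian R-squared ("explained variance") per level set.

    Per posterior draw, predictions use the fixed effects alone and then
    cumulatively add random effects of successively lower nesting levels;
    R2 = Var(yhat) / (Var(yhat) + sigma^2) is summarised by its median and
    HPD interval over draws.
    """
    X = design.X
    S = fit_result.n_draws
    yhat = X @ fit_result.beta.T                       # (n, S)
    sigma2 = fit_result.sigma ** 2
    rows = []
    for level_set in R2_LEVEL_SETS:
        if level_set != "fixed":
            level = level_set[1:]
            bl = fit_result.b[level][:, design.codes[level], :]  # (S, n, 3)
            yhat = yhat + np.einsum("nj,snj->ns", X, bl)
        var_fit = yhat.var(axis=0)                     # population variance
        r2 = var_fit / (var_fit + sigma2)
        lo, hi = hpd(r2, prob)
        rows.append({
            "level_set": level_set,
            "median": float(np.median(r2)),
            "hpd_lo": lo,
            "hpd_hi": hi,
        })
    return pd.DataFrame(rows)
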