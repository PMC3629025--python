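"""First-level GLM with AR(1) prewhitening.

The estimator follows the classical two-step (Cochrane-Orcutt) scheme used
by event-related fMRI packages: an ordinary least-squares pass, a single
global AR(1) coefficient per signal estimated from the lag-1 autocorrelation
of the residuals (pooled within runs), prewhitening of both the data and the
design with that coefficient, and a refit.  Coefficients, their covariance,
the residual variance and the AR(1) estimate are returned per signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .simulate import SignalSeries

__all__ = ["FirstLevelModel", "FirstLevelResults"]


class RankDeficientDesignError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient; names the culprits."""


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


def _lag1_autocorr(resid: np.ndarray, run: np.ndarray) -> float:
    num = 0.0
    den = float(np.sum(resid**2))
    if den == 0.0:
        return 0.0
    for r in np.unique(run):
        e = resid[run == r]
        num += float(np.sum(e[1:] * e[:-1]))
    return float(np.clip(num / den, -0.99, 0.99))


def _whiten(a: np.ndarray, run: np.ndarray, rho: float) -> np.ndarray:
    out = a.astype(float).copy()
    for r in np.unique(run):
        m = np.flatnonzero(run == r)
        seg = a[m]
        w = seg.copy()
        w[0] = seg[0] * np.sqrt(1.0 - rho**2)
        w[1:] = seg[1:] - rho * seg[:-1]
        out[m] = w
    return out


class FirstLevelModel:
    """GLM relating a :class:`~rtbold.simulate.SignalSeries` to a design.

    Parameters
    ----------
    series
        The BOLD data: a :class:`SignalSeries` or a plain
        ``(n_volumes, n_signals)`` array (then ``run`` labels are taken from
        the design).
    design
        A :class:`~rtbold.design.DesignMatrix` with matching row count.
    """

    def __init__(self, series: SignalSeries | np.ndarray, design: DesignMatrix):
        if isinstance(series, SignalSeries):
            data = series.data
            if not np.array_equal(series.run, design.run):
                raise ValueError("series and design disagree on run structure")
            self.signal_names = list(series.names)
        else:
            data = np.atleast_2d(np.asarray(series, dtype=float))
            if data.shape[0] == 1 and design.n_volumes != 1:
                data = data.T
            self.signal_names = [f"signal{i}" for i in range(data.shape[1])]
        if data.shape[0] != design.n_volumes:
            raise ValueError(
                f"series has {data.shape[0]} volumes, design has "
                f"{design.n_volumes}"
            )
        self.endog = data
        self.design = design

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, design: DesignMatrix,
                       columns: list[str] | None = None) -> "FirstLevelModel":
        """Build from a volumes x signals DataFrame (e.g. ROI series table)."""
        cols = columns or [c for c in frame.columns if c not in ("run", "time")]
        series = SignalSeries(
            data=frame[cols].to_numpy(dtype=float),
            tr=design.tr,
            run=design.run,
            names=list(cols),
        )
        return cls(series, design)

    def fit(self, prewhiten: bool = True) -> "FirstLevelResults":
        """Fit by OLS with one Cochrane-Orcutt AR(1) iteration per signal."""
        X = self.design.frame.to_numpy(dtype=float)
        names = self.design.columns
        n, p = X.shape
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            bad = _collinear_columns(X, names)
            raise RankDeficientDesignError(
                f"design is rank deficient (rank {rank} < {p} columns); "
                f"collinear or empty columns: {bad}"
            )
        run = self.design.run
        # fit on unit-norm columns: polynomial RT columns span ~15 orders of
        # magnitude in raw ms units, which would wreck the normal-equation
        # conditioning; betas and covariance are unscaled afterwards
        norms = np.linalg.norm(X, axis=0)
        norms[norms == 0] = 1.0
        Xs = X / norms
        n_signals = self.endog.shape[1]
        params = np.empty((n_signals, p))
        cov = np.empty((n_signals, p, p))
        sigma2 = np.empty(n_signals)
        ar1 = np.empty(n_signals)
        resid_out = np.empty_like(self.endog)
        for s in range(n_signals):
            y = self.endog[:, s]
            beta_s, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            resid = y - Xs @ beta_s
            rho = _lag1_autocorr(resid, run) if prewhiten else 0.0
            if prewhiten and abs(rho) > 1e-12:
                Xw = _whiten(Xs, run, rho)
                yw = _whiten(y, run, rho)
                beta_s, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            else:
                Xw, yw = Xs, y
            rw = yw - Xw @ beta_s
            df = n - p
            s2 = float(rw @ rw / df) if df > 0 else np.nan
            xtx_inv = np.linalg.inv(Xw.T @ Xw)
            params[s] = beta_s / norms
            cov[s] = s2 * (xtx_inv / np.outer(norms, norms))
            sigma2[s] = s2
            ar1[s] = rho
            resid_out[:, s] = y - X @ params[s]
        return FirstLevelResults(
            model=self,
            params=pd.DataFrame(params, index=self.signal_names, columns=names),
            cov=cov,
            sigma2=sigma2,
            ar1=ar1,
            df_resid=n - p,
            resid=resid_out,
        )


@dataclass
class FirstLevelResults:
    """Fit results: coefficients, uncertainty and AR(1) diagnostics."""

    model: FirstLevelModel
    params: pd.DataFrame  # signals x regressors
    cov: np.ndarray  # (n_signals, p, p)
    sigma2: np.ndarray
    ar1: np.ndarray
    df_resid: int
    resid: np.ndarray

    @property
    def bse(self) -> pd.DataFrame:
        se = np.sqrt(np.stack([np.diag(c) for c in self.cov]))
        return pd.DataFrame(se, index=self.params.index,
                            columns=self.params.columns)

    @property
    def tvalues(self) -> pd.DataFrame:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.DataFrame:
        t = self.tvalues.to_numpy()
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame(p, index=self.params.index,
                            columns=self.params.columns)

    def coef(self, name: str, signal: int | str = 0) -> float:
        """A single coefficient by regressor name (default: first signal)."""
        row = self.params.iloc[signal] if isinstance(signal, int) else \
            self.params.loc[signal]
        if name not in row.index:
            raise KeyError(
                f"regressor {name!r} not in fit (columns: {list(row.index)})"
            )
        return float(row[name])

    def contrast(self, weights: dict[str, float],
                 signal: int | str = 0) -> tuple[float, float, float, float]:
        """Linear contrast of coefficients -> (estimate, se, t, two-tailed p)."""
        cols = self.params.columns
        c = np.zeros(len(cols))
        for name, w in weights.items():
            if name not in cols:
                raise KeyError(f"regressor {name!r} not in fit")
            c[cols.get_loc(name)] = w
        idx = (
            signal if isinstance(signal, int)
            else self.params.index.get_loc(signal)
        )
        est = float(c @ self.params.iloc[idx].to_numpy())
        var = float(c @ self.cov[idx] @ c)
        se = float(np.sqrt(var))
        t = est / se if se > 0 else np.nan
        p = 2.0 * float(stats.t.sf(abs(t), self.df_resid)) if se > 0 else np.nan
        return est, se, t, p

    def summary(self, signal: int | str = 0) -> str:
        """Text summary of one signal's fit, statsmodels-style."""
        idx = (
            signal if isinstance(signal, int)
            else self.params.index.get_loc(signal)
        )
        name = self.params.index[idx]
        table = pd.DataFrame(
            {
                "coef": self.params.iloc[idx],
                "std err": self.bse.iloc[idx],
                "t": self.tvalues.iloc[idx],
                "P>|t|": self.pvalues.iloc[idx],
            }
        )
        lines = [
            "First-level GLM results",
            "=" * 64,
            f"signal: {name}    n volumes: {self.model.design.n_volumes}"
            f"    df resid: {self.df_resid}",
            f"AR(1) coefficient: {self.ar1[idx]:.4f}    "
            f"residual variance: {self.sigma2[idx]:.4f}",
            "-" * 64,
            table.to_string(float_format=lambda v: f"{v: .6g}"),
            "=" * 64,
        ]
        return "\n".join(lines)
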