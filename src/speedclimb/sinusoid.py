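"""Sinusoidal modelling of limb velocity signals.

Limb (ankle / wrist) velocity traces in speed climbing alternate between
acceleration and deceleration as the athlete moves between holds, and are
well described by a mono-frequent sinusoid

    v(t) = A * sin(omega * t + phi) + C.

:class:`SinusoidModel` fits this model by least squares, statsmodels-style:
the model object is built from the data, ``fit()`` returns a
:class:`SinusoidFitResult` carrying the estimates, their standard errors,
goodness of fit (R^2), the mean data-to-model peak distance, and the FFT
dominant frequency; ``summary()`` prints a table and ``plot()`` overlays the
fit on the data.

Two initialisation strategies are provided for the frequency, whose starting
value dominates convergence:

``hilbert``
    mean instantaneous frequency from the analytic-signal phase derivative
    (edge-trimmed);
``fft``
    dominant spectral frequency, refined by locally optimising from a grid
    of candidate start frequencies spanning +/-20 % around it and keeping
    the minimum-SSR solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .exceptions import (
    FitFailureError,
    MetricUndefinedError,
    NoSpectrumError,
    R2UndefinedError,
    UndefinedPhaseError,
    WindowUndefinedError,
)

#: Peak prominence threshold as a fraction of the signal's sd.
PROMINENCE_FRAC = 0.5

#: Fraction trimmed from each edge of the instantaneous-frequency series
#: before averaging (analytic-signal edge artifacts).
EDGE_TRIM_FRAC = 0.10

#: Relative half-width of the FFT refinement band around the dominant
#: frequency, and the number of candidate start frequencies in it.
REFINE_SPAN = 0.20
REFINE_STARTS = 41

#: Spectral resolution (Hz) the FFT is zero-padded to.
FFT_RESOLUTION = 0.02


def detect_peaks(v, prominence_frac: float = PROMINENCE_FRAC) -> np.ndarray:
    """Indices of local maxima with prominence >= prominence_frac * sd(v)."""
    v = np.asarray(v, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 samples")
    sd = v.std()
    if sd == 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(v, prominence=prominence_frac * sd)
    return peaks


def select_fit_window(v, prominence_frac: float = PROMINENCE_FRAC):
    """Window (start, end indices, inclusive) from first to last velocity peak."""
    peaks = detect_peaks(v, prominence_frac)
    if len(peaks) < 2:
        raise WindowUndefinedError(
            f"{len(peaks)} peak(s) detected; need >= 2 for a fit window"
        )
    return int(peaks[0]), int(peaks[-1])


def instantaneous_frequency(v, rate: float, trim_frac: float = EDGE_TRIM_FRAC):
    """Instantaneous frequency f(t) from the analytic signal, and its mean.

    The signal is mean-centred, its Hilbert analytic phase unwrapped and
    differentiated; the mean excludes ``trim_frac`` of samples at each edge.
    """
    v = np.asarray(v, dtype=float)
    if np.allclose(v, v.mean()):
        raise UndefinedPhaseError("constant signal: phase undefined")
    centred = v - v.mean()
    phase = np.unwrap(np.angle(signal.hilbert(centred)))
    f = np.gradient(phase) * rate / (2 * np.pi)
    n_trim = int(round(trim_frac * len(f)))
    core = f[n_trim:len(f) - n_trim] if n_trim and len(f) > 2 * n_trim else f
    return f, float(core.mean())


def dominant_frequency(v, rate: float, resolution: float = FFT_RESOLUTION) -> float:
    """Frequency of the maximum-magnitude spectral bin (DC excluded).

    The mean-centred signal is zero-padded so the bin spacing is at most
    ``resolution`` Hz; ties go to the lower frequency.
    """
    v = np.asarray(v, dtype=float)
    if np.allclose(v, v.mean()):
        raise NoSpectrumError("constant signal: no spectrum")
    centred = v - v.mean()
    n_fft = max(len(v), int(np.ceil(rate / resolution)))
    mag = np.abs(np.fft.rfft(centred, n_fft))
    k = 1 + int(np.argmax(mag[1:]))
    return float(k * rate / n_fft)


def initial_params(v, rate: float, strategy: str = "fft"):
    """Starting values theta0 = (A0, omega0, phi0, C0) for the fit.

    C0 = mean(v); A0 = sqrt(2) * sd(v) (exact for a pure sinusoid); phi0 = 0
    (the window starts at a peak region); omega0 = 2*pi*f with f from the
    chosen strategy.
    """
    v = np.asarray(v, dtype=float)
    c0 = float(v.mean())
    a0 = float(np.sqrt(2) * v.std())
    if strategy == "hilbert":
        _, f0 = instantaneous_frequency(v, rate)
    elif strategy == "fft":
        f0 = dominant_frequency(v, rate)
    else:
        raise ValueError(f"unknown init strategy {strategy!r}")
    return a0, 2 * np.pi * f0, 0.0, c0


def _canonicalize(theta):
    """Map (A, omega, phi, C) to the canonical form A >= 0, omega > 0,
    phi in [-pi, pi)."""
    a, w, p, c = theta
    if w < 0:
        # sin(-wt + p) = sin(wt + (pi - p)) ... via -sin(wt - p)
        w, a, p = -w, -a, -p
    if a < 0:
        a, p = -a, p + np.pi
    p = np.mod(p + np.pi, 2 * np.pi) - np.pi
    return float(a), float(w), float(p), float(c)


def model_peak_times(a, w, p, t_start, t_end):
    """Closed-form times of the sinusoid's maxima inside [t_start, t_end]."""
    if a == 0 or w == 0:
        return np.array([])
    k_lo = np.ceil((w * t_start + p - np.pi / 2) / (2 * np.pi))
    k_hi = np.floor((w * t_end + p - np.pi / 2) / (2 * np.pi))
    ks = np.arange(k_lo, k_hi + 1)
    return (np.pi / 2 - p + 2 * np.pi * ks) / w


def peak_distance(v, times, fit_params, prominence_frac: float = PROMINENCE_FRAC) -> float:
    """Mean |dt| between each data peak and its nearest model peak.

    Data peaks come from :func:`detect_peaks`; model peaks are the analytic
    maxima of the fitted sinusoid over the same span.  Each data peak is
    matched (independently) to the nearest model peak in time.
    """
    v = np.asarray(v, dtype=float)
    times = np.asarray(times, dtype=float)
    data_peaks = detect_peaks(v, prominence_frac)
    a, w, p, _ = fit_params
    mp = model_peak_times(a, w, p, times[0], times[-1])
    if len(data_peaks) == 0 or len(mp) == 0:
        raise MetricUndefinedError("no peaks available on data or model side")
    dp_times = times[data_peaks]
    return float(np.mean(np.abs(dp_times[:, None] - mp[None, :]).min(axis=1)))


@dataclass
class SinusoidFitResult:
    """Estimates and diagnostics of a sinusoidal limb-velocity fit.

    Attributes
    ----------
    params : (4,) ndarray
        Canonical (A, omega, phi, C): A >= 0 m/s, omega > 0 rad/s,
        phi in [-pi, pi), C in m/s.
    bse : (4,) ndarray
        Asymptotic standard errors from the Gauss-Newton covariance
        (NaN when the Jacobian is rank-deficient).
    ssr, sst, r2 : float
        Sum of squared residuals, total sum of squares, R^2 = 1 - SSR/SST.
    peak_distance : float
        Mean data-to-model peak time distance in seconds (NaN if undefined).
    dominant_freq : float
        FFT dominant frequency of the windowed data in Hz.
    window : (int, int)
        Fit window as (start, end) indices into the original series.
    """

    params: np.ndarray
    bse: np.ndarray
    ssr: float
    sst: float
    r2: float
    peak_distance: float
    dominant_freq: float
    window: tuple
    init_strategy: str
    nobs: int
    times: np.ndarray = None
    data: np.ndarray = None
    converged: bool = True

    param_names = ("A", "omega", "phi", "C")

    @property
    def A(self):
        return float(self.params[0])

    @property
    def omega(self):
        return float(self.params[1])

    @property
    def phi(self):
        return float(self.params[2])

    @property
    def C(self):
        return float(self.params[3])

    @property
    def frequency(self):
        """Fitted frequency in Hz (omega / 2 pi)."""
        return self.omega / (2 * np.pi)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.A * np.sin(self.omega * t + self.phi) + self.C

    def summary(self) -> str:
        units = {"A": "m/s", "omega": "rad/s", "phi": "rad", "C": "m/s"}
        lines = [
            "Sinusoidal Velocity Model Fit",
            "=" * 46,
            f"{'No. observations:':<24}{self.nobs}",
            f"{'Init strategy:':<24}{self.init_strategy}",
            f"{'R-squared:':<24}{self.r2:.4f}",
            f"{'SSR [(m/s)^2]:':<24}{self.ssr:.6g}",
            f"{'Frequency [Hz]:':<24}{self.frequency:.4f}",
            f"{'Dominant freq. [Hz]:':<24}{self.dominant_freq:.4f}",
            f"{'Peak distance [s]:':<24}{self.peak_distance:.4f}",
            "-" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}{'unit':>10}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<8}{est:>12.6f}{se:>12.4g}{units[name]:>10}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data, fitted model and residuals (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.data, ".", label="velocity data")
        tt = np.linspace(self.times[0], self.times[-1], 400)
        ax.plot(tt, self.predict(tt), label="sinusoid fit")
        ax.plot(self.times, self.data - self.predict(self.times),
                alpha=0.6, label="residuals")
        ax.set_xlabel("time [s]")
        ax.set_ylabel("velocity [m/s]")
        ax.legend()
        return ax


class SinusoidModel:
    """Least-squares mono-frequent sinusoid model for a limb velocity series.

    Parameters
    ----------
    endog : (n,) array_like
        Velocity samples in m/s.
    times : (n,) array_like, optional
        Sample times in seconds; alternatively give ``rate`` for a uniform
        grid starting at 0.
    rate : float, optional
        Sampling rate in Hz (ignored when ``times`` is given).
    window : "auto", None or (start, end)
        "auto" (default) restricts the fit to the span from the first to
        the last detected velocity peak, excluding irregular run edges;
        None uses the full series; a pair of indices is used verbatim.

    Examples
    --------
    >>> t = np.arange(0, 6, 1 / 30)
    >>> v = 1.2 * np.sin(2 * np.pi * 1.8 * t + 0.4) + 1.8
    >>> res = SinusoidModel(v, times=t, window=None).fit()
    >>> round(res.frequency, 3)
    1.8
    """

    def __init__(self, endog, times=None, rate=None, window="auto",
                 prominence_frac: float = PROMINENCE_FRAC):
        endog = np.asarray(endog, dtype=float)
        if times is not None:
            times = np.asarray(times, dtype=float)
            if len(times) != len(endog):
                raise ValueError("times and endog lengths differ")
            rate = 1.0 / float(np.median(np.diff(times)))
        elif rate is not None:
            times = np.arange(len(endog)) / float(rate)
        else:
            raise ValueError("supply either times or rate")
        self.endog = endog
        self.times = times
        self.rate = float(rate)
        self.prominence_frac = prominence_frac
        if window == "auto":
            window = select_fit_window(endog, prominence_frac)
        elif window is None:
            window = (0, len(endog) - 1)
        self.window = (int(window[0]), int(window[1]))
        i0, i1 = self.window
        if not (0 <= i0 < i1 <= len(endog) - 1):
            raise ValueError("invalid fit window")
        self._t = times[i0:i1 + 1]
        self._v = endog[i0:i1 + 1]

    @classmethod
    def from_dataframe(cls, df, value_col: str = "velocity",
                       time_col: str = "time_s", **kwargs) -> "SinusoidModel":
        return cls(df[value_col].to_numpy(), times=df[time_col].to_numpy(),
                   **kwargs)

    # -- fitting ---------------------------------------------------------

    @staticmethod
    def _predict(theta, t):
        a, w, p, c = theta
        return a * np.sin(w * t + p) + c

    def _local_fit(self, theta0, tight=True):
        tol = 1e-15 if tight else 1e-9
        res = optimize.least_squares(
            lambda th: self._predict(th, self._t) - self._v,
            theta0, method="lm", xtol=tol, ftol=tol, gtol=tol,
            max_nfev=2000,
        )
        return res

    def _screen_frequencies(self, freqs, n_keep=3):
        """Rank candidate frequencies by their exact conditional-LS SSR."""
        t, v = self._t, self._v
        ssrs = []
        for f in freqs:
            w = 2 * np.pi * f
            X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
            _, res, rank, _ = np.linalg.lstsq(X, v)
            if rank < 3 or len(res) == 0:
                ssrs.append(np.inf)
            else:
                ssrs.append(float(res[0]))
        order = np.argsort(ssrs)
        return [freqs[i] for i in order[:n_keep]]

    def fit(self, strategy: str = "fft", refine: bool = True,
            n_starts: int = REFINE_STARTS,
            refine_span: float = REFINE_SPAN) -> SinusoidFitResult:
        """Minimise the SSR from strategy-dependent starting values.

        With the ``fft`` strategy and ``refine=True``, ``n_starts``
        equally spaced candidate start frequencies spanning
        dominant_freq * (1 +/- refine_span) are each locally optimised and
        the minimum-SSR solution kept.
        """
        v, t = self._v, self._t
        sst = float(np.sum((v - v.mean()) ** 2))
        if sst == 0:
            raise R2UndefinedError("constant data: SST = 0, R^2 undefined")
        a0, w0, p0, c0 = initial_params(v, self.rate, strategy)
        if strategy == "fft" and refine:
            f_d = w0 / (2 * np.pi)
            freqs = np.linspace(f_d * (1 - refine_span),
                                f_d * (1 + refine_span), n_starts)
        else:
            freqs = [w0 / (2 * np.pi)]
        best = None
        any_success = False
        theta0_ssr = float(np.sum((self._predict((a0, w0, p0, c0), t) - v) ** 2))
        if len(freqs) > 1:
            # screen the frequency grid by variable projection: at fixed
            # omega the model a*sin(wt) + b*cos(wt) + C is linear, so the
            # SSR-minimising start per candidate is a closed-form solve
            starts = [(a0, 2 * np.pi * f, p0, c0)
                      for f in self._screen_frequencies(freqs, n_keep=3)]
        else:
            starts = [(a0, 2 * np.pi * freqs[0], p0, c0)]
        for theta0 in starts:
            res = self._local_fit(theta0, tight=True)
            any_success = any_success or res.success
            if best is None or res.cost < best.cost:
                best = res
        ssr = float(2 * best.cost)
        if ssr > theta0_ssr:  # optimizer must never be worse than the start
            ssr = theta0_ssr
            theta = _canonicalize((a0, w0, p0, c0))
            jac = None
        else:
            theta = _canonicalize(best.x)
            jac = best.jac
        r2 = 1.0 - ssr / sst
        bse = np.full(4, np.nan)
        if jac is not None and len(v) > 4:
            try:
                jtj = jac.T @ jac
                cov = np.linalg.inv(jtj) * ssr / (len(v) - 4)
                bse = np.sqrt(np.abs(np.diag(cov)))
            except np.linalg.LinAlgError:
                pass
        try:
            pdist = peak_distance(v, t, theta, self.prominence_frac)
        except MetricUndefinedError:
            pdist = float("nan")
        fd = dominant_frequency(v, self.rate)
        result = SinusoidFitResult(
            params=np.array(theta), bse=bse, ssr=ssr, sst=sst, r2=r2,
            peak_distance=pdist, dominant_freq=fd, window=self.window,
            init_strategy=strategy, nobs=len(v), times=t, data=v,
            converged=any_success,
        )
        if not any_success:
            raise FitFailureError("optimizer failed from every start",
                                  best_result=result)
        return result


def fit_sinusoid(v, rate: float = None, times=None, strategy: str = "fft",
                 window: object = "auto", **fit_kwargs) -> SinusoidFitResult:
    """Functional wrapper: build a :class:`SinusoidModel` and fit it."""
    return SinusoidModel(v, times=times, rate=rate,
                         window=window).fit(strategy=strategy, **fit_kwargs)
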