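"""Independent oracle implementations used only by the tests.

These are deliberately naive, scalar, day-by-day transcriptions of the
governing equations (standard-library math only in the inner loops), kept
separate from the package so that agreement between the two code paths is a
meaningful check and not a tautology.
"""

from __future__ import annotations

import math

# -- solar geometry (scalar, independent of the package's vectorized code) ----


def oracle_declination(doy: int) -> float:
    return 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)


def oracle_sunset_hour_angle(lat_deg: float, doy: int) -> float:
    phi = math.radians(lat_deg)
    x = -math.tan(phi) * math.tan(oracle_declination(doy))
    x = min(1.0, max(-1.0, x))
    return math.acos(x)


def oracle_ra(lat_deg: float, doy: int) -> float:
    """FAO-56 extraterrestrial radiation, MJ m-2 day-1."""
    gsc = 0.0820
    phi = math.radians(lat_deg)
    delta = oracle_declination(doy)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    ws = oracle_sunset_hour_angle(lat_deg, doy)
    ra = (24.0 * 60.0 / math.pi) * gsc * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )
    return max(ra, 0.0)


def oracle_daylength(lat_deg: float, doy: int) -> float:
    return 24.0 / math.pi * oracle_sunset_hour_angle(lat_deg, doy)


def oracle_et0(lat_deg: float, doy: int, tmin: float, tmax: float, precip: float) -> float:
    """Modified Hargreaves-Samani (Droogers & Allen constants)."""
    ra = oracle_ra(lat_deg, doy)
    tavg = 0.5 * (tmin + tmax)
    radicand = max((tmax - tmin) - 0.0123 * precip, 0.0)
    et0 = 0.0013 * 0.408 * ra * (tavg + 17.0) * radicand**0.76
    return max(et0, 0.0)


# -- phenology day loops ------------------------------------------------------


def _vern_effectiveness(tavg: float, curve) -> float:
    pts = list(curve)
    if tavg <= pts[0][0] or tavg >= pts[-1][0]:
        return 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if x0 <= tavg <= x1:
            return y0 + (y1 - y0) * (tavg - x0) / (x1 - x0)
    return 0.0


def _vf(state: float, vern) -> float:
    if vern is None:
        return 1.0
    v = (state - vern.v_base) / (vern.v_sat - vern.v_base)
    return min(1.0, max(0.0, v))


def _pf(lat: float, doy: int, photo) -> float:
    if photo is None:
        return 1.0
    dl = oracle_daylength(lat, doy)
    p = (dl - photo.d_critical) / (photo.d_optimal - photo.d_critical)
    return min(1.0, max(0.0, p))


def oracle_dvs_2phase(tavg, doys, latitude, params) -> list[float]:
    """Literal day loop of the two-phase development equation.

    ``tavg``/``doys`` start at the sowing day (index 0, DVS 0); Vf and Pf
    multiply the capped effective-temperature increment while DVS < 1, and a
    day crossing DVS = 1 splits its thermal time between the two phases.
    """
    dvs = [0.0]
    state = 0.0
    vern_state = 0.0
    for i in range(1, len(tavg)):
        if params.vern is not None:
            vern_state += _vern_effectiveness(tavg[i], params.vern.curve)
        if state >= 2.0:
            dvs.append(2.0)
            continue
        eff = max(0.0, min(tavg[i] - params.t_base, params.t_max_eff))
        if state < 1.0:
            inc = (
                eff
                * _vf(vern_state, params.vern)
                * _pf(latitude, int(doys[i]), params.photo)
                / params.tsum1
            )
            if state + inc <= 1.0:
                state += inc
            else:
                used = (1.0 - state) / inc if inc > 0 else 1.0
                state = 1.0 + (1.0 - used) * eff / params.tsum2
        else:
            state += eff / params.tsum2
        state = min(state, 2.0)
        dvs.append(state)
    return dvs


def oracle_dvs_multiphase(tavg, doys, latitude, params) -> list[float]:
    """Literal day loop of the six-sub-phase development equation."""
    dvs = [0.0]
    state = 0.0
    vern_state = 0.0
    for i in range(1, len(tavg)):
        if params.vern is not None:
            vern_state += _vern_effectiveness(tavg[i], params.vern.curve)
        if state >= 6.0:
            dvs.append(6.0)
            continue
        phase = min(int(math.floor(state)) + 1, 6)
        vf = _vf(vern_state, params.vern)
        pf = _pf(latitude, int(doys[i]), params.photo)
        corr = vf * pf if 2 <= phase <= 5 else 1.0
        eff = max(0.0, min(tavg[i] - params.t_bases[phase - 1], params.t_max_eff))
        inc = eff * corr / params.tsums[phase - 1]
        if state + inc <= phase:
            state += inc
        else:
            used = (phase - state) / inc if inc > 0 else 1.0
            state = float(phase)
            if phase < 6:
                nxt = phase + 1
                corr2 = vf * pf if 2 <= nxt <= 5 else 1.0
                eff2 = max(0.0, min(tavg[i] - params.t_bases[nxt - 1], params.t_max_eff))
                state = min(state + (1.0 - used) * eff2 * corr2 / params.tsums[nxt - 1], float(nxt))
        state = min(state, 6.0)
        dvs.append(state)
    return dvs


# -- indicator recomputation --------------------------------------------------


def oracle_count(values, threshold: float, direction: str) -> int:
    n = 0
    for v in values:
        if (direction == "above" and v > threshold) or (
            direction == "below" and v < threshold
        ):
            n += 1
    return n


def oracle_max_consecutive(values, threshold: float, direction: str) -> int:
    best = run = 0
    for v in values:
        ok = v > threshold if direction == "above" else v < threshold
        run = run + 1 if ok else 0
        if run > best:
            best = run
    return best


def oracle_spei_rank(value: float, reference) -> float:
    """Rank-based empirical probability -> normal quantile, via explicit
    counting and the scipy inverse normal CDF."""
    from scipy.stats import norm

    less = sum(1 for r in reference if r < value)
    equal = sum(1 for r in reference if r == value)
    rank = less + 0.5 * (equal + 1)
    return float(norm.ppf(rank / (len(reference) + 1.0)))
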