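"""Independent brute-force reference implementations used only by tests.

Each oracle is a direct sample-by-sample transliteration of the stated rule,
written without reference to the library internals, so agreement between the
two is evidence the library implements the rule it documents.
"""

from __future__ import annotations

import math


def mdm_oracle(xy, threshold: float) -> list[int]:
    """Greedy minimum-distance acceptance, first sample always kept."""
    if len(xy) == 0:
        return []
    kept = [0]
    for i in range(1, len(xy)):
        ax, ay = xy[kept[-1]]
        bx, by = xy[i]
        if math.dist((ax, ay), (bx, by)) >= threshold:
            kept.append(i)
    return kept


def rotation_oracle(headings, threshold: float) -> tuple[int, int]:
    """(cw, ccw) full-turn counts, tracking heading extrema explicitly.

    The walker keeps the extreme heading reached in the current direction and
    the heading where the current run started. Moving further in the current
    direction advances the extreme; retreating from the extreme by at least
    ``threshold`` starts a new run at that extreme, in the other direction.
    A full turn is counted whenever the extreme is a full circle past the
    run's start, which then advances by a full circle.
    """
    hs = [h for h in headings if h == h]  # drop NaN
    if len(hs) < 2:
        return 0, 0
    cw = ccw = 0
    direction = 0
    start = extreme = hs[0]
    for h in hs[1:]:
        if direction == 0:
            if h > start:
                direction = 1
            elif h < start:
                direction = -1
            extreme = h
        elif direction == 1:
            if h > extreme:
                extreme = h
            elif extreme - h >= threshold:
                direction, start, extreme = -1, extreme, h
        else:
            if h < extreme:
                extreme = h
            elif h - extreme >= threshold:
                direction, start, extreme = 1, extreme, h
        while direction == 1 and extreme - start >= 360.0:
            ccw += 1
            start += 360.0
        while direction == -1 and start - extreme >= 360.0:
            cw += 1
            start -= 360.0
    return cw, ccw


def meander_oracle(xy) -> tuple[float, float]:
    """(per-step mean, aggregate) |turn|/distance in deg/cm of a polyline."""
    if len(xy) < 3:
        return float("nan"), float("nan")
    vals = []
    tsum = dsum = 0.0
    for i in range(1, len(xy) - 1):
        a1 = math.degrees(
            math.atan2(xy[i][1] - xy[i - 1][1], xy[i][0] - xy[i - 1][0])
        )
        a2 = math.degrees(
            math.atan2(xy[i + 1][1] - xy[i][1], xy[i + 1][0] - xy[i][0])
        )
        turn = abs((a2 - a1 + 180.0) % 360.0 - 180.0)
        d = math.dist(tuple(xy[i]), tuple(xy[i + 1]))
        vals.append(turn / d)
        tsum += turn
        dsum += d
    return sum(vals) / len(vals), tsum / dsum


def events_oracle(values, threshold: float, min_samples: int,
                  above: bool = True) -> int:
    """Count maximal supra(/sub)-threshold runs of at least min_samples.

    Low runs use the same 1e-9 numerical zero floor as the detector: values
    below it are differencing dust, not a positive-acceleration state.
    """
    count = 0
    run = 0
    for v in values:
        hit = (v > threshold) if above else (1e-9 < v <= threshold)
        if v != v:
            hit = False
        if hit:
            run += 1
        else:
            if run >= min_samples:
                count += 1
            run = 0
    if run >= min_samples:
        count += 1
    return count


def hysteresis_oracle(v, start: float, stop: float) -> list[str]:
    """Per-sample movement labels: 'U' undefined, 'M' moving, 'N' not."""
    state = "U"
    out = []
    for x in v:
        if x != x:
            state = "U"
        elif state == "M":
            if x < stop:
                state = "N"
        elif state == "N":
            if x > start:
                state = "M"
        else:
            if x > start:
                state = "M"
            elif x < stop:
                state = "N"
        out.append(state)
    return out
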