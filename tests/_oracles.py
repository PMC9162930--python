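"""Independent reference implementations used only for cross-checking.

These deliberately avoid the package's code paths: the run-enumeration
oracle lists every contiguous above-threshold run and reads the answer
off directly; the row-gap oracle transcribes the data-table idiom of
consecutive row numbers, a duplicated first row and a diff != 1 search.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np


def runs_above(intensity, threshold):
    """All contiguous runs of samples strictly above threshold, as (start, end)."""
    runs = []
    start = None
    for i, v in enumerate(intensity):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(intensity) - 1))
    return runs


def oracle_boundaries(
    intensity, threshold, id_max, contiguous_lower: bool
) -> Tuple[Optional[int], Optional[int]]:
    """(lower, upper) by exhaustive run enumeration.

    Upper: last index of the run containing id_max (None if id_max is not
    above threshold). Lower: first above-threshold index at or before
    id_max, or the start of id_max's run when contiguous_lower.
    """
    my_run = None
    for s, e in runs_above(intensity, threshold):
        if s <= id_max <= e:
            my_run = (s, e)
            break
    upper = my_run[1] if my_run else None
    if contiguous_lower:
        lower = my_run[0] if my_run else None
    else:
        lower = None
        for i in range(id_max + 1):
            if intensity[i] > threshold:
                lower = i
                break
    return lower, upper


def rowgap_boundaries(intensity, threshold, id_max) -> Tuple[Optional[int], Optional[int]]:
    """(beginning, end) via the row-number/gap idiom.

    Rows are numbered consecutively; sub-threshold rows are dropped (NA);
    the first kept row is duplicated so that its diff of 0 registers as a
    gap; the biofilm end is the row before the first diff != 1 among rows
    past the peak, and the beginning is the first gap row at or before
    the peak.
    """
    kept = [i for i, v in enumerate(intensity) if v > threshold]
    if id_max not in kept:
        return None, None
    doubled = [kept[0]] + kept
    diffs = [doubled[j + 1] - doubled[j] for j in range(len(kept))]

    beginning = None
    for j, d in enumerate(diffs):
        if d != 1 and kept[j] <= id_max:
            beginning = kept[j]
            break

    end = kept[-1]
    for j, d in enumerate(diffs):
        if d != 1 and kept[j] > id_max:
            end = kept[j - 1]
            break
    return beginning, end


def iter_mask_cases(max_len: int):
    """Every distinct (length, above-mask, peak-position) boundary scenario.

    At a fixed threshold the boundary operations depend on the profile
    only through which samples are above threshold and where the peak
    index sits, so one representative profile per (mask, id_max) class
    covers the full value grid of that length. Values are drawn from
    {0, 1, 4, 9} with threshold 3: peak 9, other above samples 4,
    below-threshold samples alternating 0/1.
    """
    for n in range(3, max_len + 1):
        for bits in range(1, 2**n):
            mask = [(bits >> i) & 1 == 1 for i in range(n)]
            for id_max in range(n):
                if not mask[id_max]:
                    continue
                vals = np.array(
                    [(4.0 if m else float(i % 2)) for i, m in enumerate(mask)]
                )
                vals[id_max] = 9.0
                yield vals, id_max
        # all-below masks: no sample above threshold, any peak position
        for id_max in range(n):
            vals = np.array([float(i % 2) for i in range(n)])
            vals[id_max] = 1.0
            yield vals, id_max
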