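"""Tucson decadal (.rwl) ring-width format.

Each line carries a series ID (8 columns), the decade's first year
(4 columns) and up to ten 6-column integer widths. The stop marker
doubles as the units flag: ``999`` for 0.01 mm precision, ``-9999``
for 0.001 mm. Both are honoured on read; write defaults to 0.001 mm.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .growth import RingSeries

_STOP_001 = -9999  # 0.001 mm units
_STOP_01 = 999     # 0.01 mm units


def read_rwl(path) -> list[RingSeries]:
    """Read all series from a Tucson decadal file."""
    values: dict[str, dict[int, float]] = {}
    done: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if len(rest) < 2:
                raise ValidationError(f"malformed rwl line: {line!r}")
            year = int(rest[0])
            store = values.setdefault(sid, {})
            for i, tok in enumerate(rest[1:]):
                v = int(tok)
                if v == _STOP_001:
                    scale = 0.001
                    done.add(sid)
                    store["__scale__"] = scale
                    break
                if v == _STOP_01:
                    scale = 0.01
                    done.add(sid)
                    store["__scale__"] = scale
                    break
                store[year + i] = float(v)
    out = []
    for sid, store in values.items():
        scale = store.pop("__scale__", 0.001)
        if sid not in done:
            raise ValidationError(f"series {sid} missing stop marker")
        years = sorted(store)
        if not years:
            raise ValidationError(f"series {sid} is empty")
        if years != list(range(years[0], years[-1] + 1)):
            raise ValidationError(f"series {sid} has year gaps")
        widths = np.array([store[y] for y in years]) * scale
        out.append(RingSeries(sid, years[0], widths))
    return out


def write_rwl(path, series_list: list[RingSeries], units=0.001) -> None:
    """Write series in Tucson decadal format.

    ``units`` is the measurement precision in mm (0.001 or 0.01) and
    selects the matching stop marker.
    """
    if units == 0.001:
        stop = _STOP_001
    elif units == 0.01:
        stop = _STOP_01
    else:
        raise ValidationError("units must be 0.001 or 0.01 mm")
    with open(path, "w") as fh:
        for s in series_list:
            sid = s.tree_id[:8]
            vals = np.rint(s.widths / units).astype(int)
            year = s.first_year
            i = 0
            while i < len(vals):
                decade_end = (year // 10) * 10 + 9
                take = min(decade_end - year + 1, len(vals) - i)
                chunk = vals[i:i + take]
                fields = "".join(f"{v:6d}" for v in chunk)
                last_chunk = i + take == len(vals)
                if last_chunk and take < 10:
                    fields += f"{stop:6d}"
                fh.write(f"{sid:<8s}{year:4d}{fields}\n")
                if last_chunk and take == 10:
                    fh.write(f"{sid:<8s}{year + take:4d}{stop:6d}\n")
                year += take
                i += take
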