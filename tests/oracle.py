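"""Brute-force reference detector used only as a test oracle.

Independent of the production state machine: it compresses the frames that
commit a terminal compartment into runs and scans consecutive runs for
crossing patterns. EC<->vestibule crossings are classified by the
same rule as the production code — lateral when the transit shows a raw
FENESTRATION frame or the relevant frame-pair segment pierces the side wall
inside the fenestration band, apical when it pierces the ceiling disc within
the apical radius — but the surface-crossing points are located by bisection
on the exact geometry instead of the closed-form interpolation used in
production.
"""

from fenestra.geometry import Region, assign_region, region_with_margin
from fenestra.tracks import unwrap_track


def _bisect(f, lo, hi, iters=80):
    """Root of f on [lo, hi] assuming a single sign change."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if (f(mid) > 0) == (flo > 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _point(p0, p1, t):
    return tuple(a + t * (b - a) for a, b in zip(p0, p1))


def _classify_pair(p0, p1, model, entering):
    """Classify one frame-pair crossing of the vestibule boundary."""
    top = model.z_vest_top
    z0, z1 = p0[2], p1[2]
    if (z0 - top) * (z1 - top) < 0:
        t = _bisect(lambda t: _point(p0, p1, t)[2] - top, 0.0, 1.0)
        q = _point(p0, p1, t)
        if model.radial(q[0], q[1]) <= model.r_apical:
            return "apical"
    r0 = model.radial(p0[0], p0[1])
    r1 = model.radial(p1[0], p1[1])
    if (r0 - model.r_vest) * (r1 - model.r_vest) < 0:
        t = _bisect(
            lambda t: model.radial(*_point(p0, p1, t)[:2]) - model.r_vest, 0.0, 1.0
        )
        z_cross = _point(p0, p1, t)[2]
        if model.fen_band[0] <= z_cross <= model.fen_band[1]:
            return "lateral"
    z_out = z0 if entering else z1
    return "apical" if z_out > top else "lateral"


def _access_pathway(pos, seg_raw, a_last, b_first, model, entering):
    """lateral/apical for the EC<->vestibule leg of a transit segment."""
    if Region.FENESTRATION in seg_raw:
        return "lateral"
    if entering:  # last frame pair stepping into the vestibule
        pairs = [
            j
            for j in range(a_last, b_first)
            if seg_raw[j - a_last] != Region.VESTIBULE
            and seg_raw[j + 1 - a_last] == Region.VESTIBULE
        ]
        j = pairs[-1] if pairs else None
    else:  # first frame pair stepping out of it
        pairs = [
            j
            for j in range(a_last, b_first)
            if seg_raw[j - a_last] == Region.VESTIBULE
            and seg_raw[j + 1 - a_last] != Region.VESTIBULE
        ]
        j = pairs[0] if pairs else None
    if j is None:
        z_out = pos[a_last][2] if entering else pos[b_first][2]
        return "apical" if z_out > model.z_vest_top else "lateral"
    return _classify_pair(pos[j], pos[j + 1], model, entering)


def oracle_events(track, model):
    track = unwrap_track(track)
    pos = track.positions
    # runs of frames *committed* in a terminal label: [first, last, label];
    # frames that commit nothing (or a transit region) never extend a run
    runs = []
    prev = None
    for i, p in enumerate(pos):
        lab = region_with_margin(p, model, model.hysteresis)
        if lab in Region.TERMINAL:
            if lab != prev:
                runs.append([i, i, lab])
                prev = lab
            else:
                runs[-1][1] = i

    events = []
    for (_, a_last, a), (b_first, _, b) in zip(runs, runs[1:]):
        seg_raw = [assign_region(pos[j], model) for j in range(a_last, b_first + 1)]
        t = float(track.times[b_first])
        if {a, b} == {Region.VESTIBULE, Region.IC}:
            events.append(("transmembrane", "inward" if b == Region.IC else "outward", t))
        elif {a, b} == {Region.VESTIBULE, Region.EC}:
            entering = b == Region.VESTIBULE
            pathway = _access_pathway(pos, seg_raw, a_last, b_first, model, entering)
            events.append((pathway, "inward" if entering else "outward", t))
        else:  # direct IC<->EC: decompose
            if b == Region.IC:
                pathway = _access_pathway(pos, seg_raw, a_last, b_first, model, True)
                events.append((pathway, "inward", t))
                events.append(("transmembrane", "inward", t))
            else:
                events.append(("transmembrane", "outward", t))
                pathway = _access_pathway(pos, seg_raw, a_last, b_first, model, False)
                events.append((pathway, "outward", t))
    return events
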