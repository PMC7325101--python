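"""Independent scalar expected-value recursion for tiny cohort instances.

Deliberately written with plain Python loops and dictionaries — no shared
code with the vectorised engine — so it can serve as an oracle for
``advance_year`` on instances with a handful of compartments.
Covers one (sex, age band) cell at a time.
"""

from piburden.ontology import HEALTH_STATES


def advance_cell(counts, rates, bridge, history, ontology, s, a):
    """One annual cycle for a single (sex, age) cell.

    Parameters
    ----------
    counts
        dict ``(stratum_index, state_name) -> persons``.
    rates
        dict with per-stratum lists ``t2d``, ``chd``, ``stroke`` and scalar
        ``non_cvd_death`` for the CVD-free state.
    bridge, history, ontology
        the same parameter objects the engine uses; only scalars for
        ``(s, a)`` are read.

    Returns
    -------
    (new_counts, tallies) with tallies for the six outcomes plus
    ``chd_events``, ``stroke_events`` and ``deaths_total``.
    """
    tab = ontology.table()
    diab_col = list(tab["diabetes"])
    levels = ontology.factors["diabetes"]

    def diabetes_partner(k):
        want = dict(tab.iloc[k])
        want["diabetes"] = levels[1] if want["diabetes"] == levels[0] else levels[0]
        for j in range(len(tab)):
            if dict(tab.iloc[j]) == want:
                return j
        raise AssertionError("no partner stratum")

    ffrac = sum(
        bridge.chd_type_split[s, a, t] * bridge.chd_case_fatality[s, a, t]
        for t in range(3)
    )
    mi_frac = bridge.chd_type_split[s, a, 1]
    cf_mi = bridge.chd_case_fatality[s, a, 1]
    cf_stroke = bridge.stroke_case_fatality[s, a]

    new = {key: 0.0 for key in counts}
    for key, val in counts.items():
        new[key] = val
    tallies = {
        k: 0.0
        for k in (
            "t2d_incidence",
            "chd_incidence",
            "stroke_incidence",
            "total_mi",
            "chd_mortality",
            "stroke_mortality",
            "chd_events",
            "stroke_events",
            "deaths_total",
        )
    }

    for k in range(len(tab)):
        n = counts.get((k, "no_cvd"), 0.0)
        if n == 0.0:
            continue
        ev_t2d = n * rates["t2d"][k] if diab_col[k] == levels[0] else 0.0
        ev_chd = n * rates["chd"][k]
        ev_stroke = n * rates["stroke"][k]
        d_ncd = n * rates["non_cvd_death"]
        chd_fatal = ev_chd * ffrac
        stroke_fatal = ev_stroke * cf_stroke

        new[(k, "no_cvd")] -= ev_t2d + ev_chd + ev_stroke + d_ncd
        partner = diabetes_partner(k)
        new[(partner, "no_cvd")] = new.get((partner, "no_cvd"), 0.0) + ev_t2d
        new[(k, "post_chd")] = new.get((k, "post_chd"), 0.0) + ev_chd - chd_fatal
        new[(k, "post_stroke")] = (
            new.get((k, "post_stroke"), 0.0) + ev_stroke - stroke_fatal
        )

        tallies["t2d_incidence"] += ev_t2d
        tallies["chd_incidence"] += ev_chd
        tallies["stroke_incidence"] += ev_stroke
        tallies["total_mi"] += ev_chd * mi_frac
        tallies["chd_mortality"] += chd_fatal
        tallies["stroke_mortality"] += stroke_fatal
        tallies["chd_events"] += ev_chd
        tallies["stroke_events"] += ev_stroke
        tallies["deaths_total"] += d_ncd + chd_fatal + stroke_fatal

    for j, state in enumerate(HEALTH_STATES[1:]):
        for k in range(len(tab)):
            m = counts.get((k, state), 0.0)
            if m == 0.0:
                continue
            chd_ev = m * history.chd_event_rate[s, a, j]
            st_ev = m * history.stroke_event_rate[s, a, j]
            cvd_d = m * history.cvd_death_rate[s, a, j]
            ncd_d = m * history.non_cvd_death_rate[s, a, j]
            if state == "post_chd":
                chd_f = chd_ev * cf_mi
                st_f = st_ev * cf_stroke
                new[(k, state)] -= chd_f + st_ev + cvd_d + ncd_d
                new[(k, "post_both")] = new.get((k, "post_both"), 0.0) + st_ev - st_f
                tallies["stroke_incidence"] += st_ev
                tallies["total_mi"] += chd_ev
                tallies["chd_mortality"] += chd_f + cvd_d
                tallies["stroke_mortality"] += st_f
            elif state == "post_stroke":
                chd_f = chd_ev * ffrac
                st_f = st_ev * cf_stroke
                new[(k, state)] -= chd_ev + st_f + cvd_d + ncd_d
                new[(k, "post_both")] = new.get((k, "post_both"), 0.0) + chd_ev - chd_f
                tallies["chd_incidence"] += chd_ev
                tallies["total_mi"] += chd_ev * mi_frac
                tallies["chd_mortality"] += chd_f
                tallies["stroke_mortality"] += st_f + cvd_d
            else:
                chd_f = chd_ev * cf_mi
                st_f = st_ev * cf_stroke
                new[(k, state)] -= chd_f + st_f + cvd_d + ncd_d
                share = history.chd_share_both
                tallies["total_mi"] += chd_ev
                tallies["chd_mortality"] += chd_f + share * cvd_d
                tallies["stroke_mortality"] += st_f + (1 - share) * cvd_d
            tallies["chd_events"] += chd_ev
            tallies["stroke_events"] += st_ev
            tallies["deaths_total"] += chd_f + st_f + cvd_d + ncd_d

    return new, tallies
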