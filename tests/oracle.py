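"""Independent brute-force re-implementation of the analysis rules.

Pure-Python double loops over (condition x stratum), no pandas and no reuse
of package internals: this is the reference the vectorized pipeline is
checked against on small instances.  Records are plain tuples:
``(intervention_id, (method, theme, setting), ratings_dict, selections)``.
"""

import re


def _norm(text):
    return re.sub(r"\s+", " ", str(text)).strip().casefold()


def oracle_resolve(selections, condition_ids, recode_map):
    resolved = set()
    for entry in selections:
        entry = str(entry)
        if entry in condition_ids:
            resolved.add(entry)
        else:
            mapped = (recode_map or {}).get(_norm(entry))
            if mapped is not None:
                resolved.add(mapped)
    return resolved


def oracle_flags(records, condition_ids, recode_map=None):
    """{(intervention_id, condition_id): (suboptimal, important, bottleneck)}"""
    flags = {}
    for rec_id, _system, ratings, selections in records:
        important = oracle_resolve(selections, condition_ids, recode_map)
        for cid in condition_ids:
            rating = ratings.get(cid)
            sub = rating is not None and rating != 5
            imp = cid in important
            flags[(rec_id, cid)] = (sub, imp, sub and imp)
    return flags


def oracle_frequent_systems(records, min_count=10):
    tally = {}
    for _rec_id, system, _r, _s in records:
        tally[system] = tally.get(system, 0) + 1
    return {system for system, n in tally.items() if n > min_count}


def oracle_strata(records, min_count=10):
    """{(kind, key): [intervention ids]} for every non-empty stratum."""
    strata = {}
    for system in oracle_frequent_systems(records, min_count):
        strata[("frequent_system", system)] = [
            rec_id for rec_id, s, _r, _sel in records if s == system
        ]
    for pos, kind in enumerate(("method", "theme", "setting")):
        for level in {s[pos] for _i, s, _r, _sel in records}:
            strata[(kind, level)] = [
                rec_id for rec_id, s, _r, _sel in records if s[pos] == level
            ]
    if records:
        strata[("all", "all")] = [rec_id for rec_id, _s, _r, _sel in records]
    return strata


def oracle_stratum_calls(members, flags, condition_ids):
    """{condition_id: (n_flagged, is_bottleneck)} with the strict >10% rule,
    decided in integer arithmetic (10 * flagged > members)."""
    calls = {}
    for cid in condition_ids:
        n_flagged = sum(1 for rec_id in members if flags[(rec_id, cid)][2])
        calls[cid] = (n_flagged, 10 * n_flagged > len(members))
    return calls


def oracle_labels(records, condition_ids, min_count=10, recode_map=None):
    """{(system, condition_id): label} over frequent systems, existential
    reading of the characteristic association."""
    flags = oracle_flags(records, condition_ids, recode_map)
    strata = oracle_strata(records, min_count)
    calls = {
        key: oracle_stratum_calls(members, flags, condition_ids)
        for key, members in strata.items()
    }
    labels = {}
    for (kind, system), _members in strata.items():
        if kind != "frequent_system":
            continue
        for cid in condition_ids:
            in_system = calls[("frequent_system", system)][cid][1]
            in_char = any(
                calls[(char, system[pos])][cid][1]
                for pos, char in enumerate(("method", "theme", "setting"))
            )
            if in_system and in_char:
                label = "EPB"
            elif in_system:
                label = "UPB"
            elif in_char:
                label = "UAB"
            else:
                label = "concordant_absent"
            labels[(system, cid)] = label
    return labels
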