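"""Shared end-to-end pipeline drivers used by several test modules."""

from __future__ import annotations

import numpy as np

from lethalmap.complementation_mapping import (
    build_allelism_graph,
    call_deficiency_mapping,
    call_deficiency_mapping_table,
)
from lethalmap.synthetic_data import (
    SimConfig,
    simulate_allelism_crosses,
    simulate_cross,
    simulate_screen,
    simulate_variant_tables,
)
from lethalmap.variant_filtering import filter_candidates


def allelism_pairs_from_calls(calls):
    """Pairs of lethal lines mapped to the same deficiency (the screen's
    criterion for running an allelism cross)."""
    pairs = set()
    mapped = calls[calls["call"] == "mapped"]
    for _, grp in mapped.groupby("tester_id"):
        ids = sorted(grp["line_id"].unique())
        pairs.update((a, b) for i, a in enumerate(ids) for b in ids[i + 1 :])
    return sorted(pairs)


def gene_resolved_sets(bundle, config: SimConfig, rng: np.random.Generator):
    """Reproduce the screen's fine-mapping: allelism graph -> components ->
    per-gene knock-out crosses -> gene-resolved allelic sets.

    Returns (sets, lethal_lines) where each set is (gene_id, member line ids).
    """
    lethal = {s.subline_id: s.chromosome for s in bundle.sublines if s.lethal}
    calls = call_deficiency_mapping_table(bundle.deficiency_crosses)
    pairs = allelism_pairs_from_calls(calls)
    graph = build_allelism_graph(simulate_allelism_crosses(lethal, pairs, config, rng))

    catalog = bundle.population.catalog
    panel = bundle.panel.deficiencies.set_index("deficiency_id")
    mapped = calls[calls["call"] == "mapped"]
    mapped_by_line = mapped.groupby("line_id")["tester_id"].apply(set)

    sets = []
    for comp in graph.components:
        members = sorted(comp)
        # deficiencies mapped by at least two members bound the search region
        from collections import Counter

        df_counts = Counter(
            d for m in members for d in mapped_by_line.get(m, set())
        )
        genes_to_test = set()
        for d, cnt in df_counts.items():
            if cnt < 2:
                continue
            s, e = panel.loc[d, "start"], panel.loc[d, "end"]
            hits = np.flatnonzero((catalog.starts <= e) & (catalog.ends >= s))
            genes_to_test.update(int(g) for g in hits)
        for g in sorted(genes_to_test):
            failing = []
            for m in members:
                res = simulate_cross(lethal[m], ("knockout", g), config, rng, line_id=m)
                if call_deficiency_mapping(res).call == "mapped":
                    failing.append(m)
            if len(failing) >= 2:
                sets.append((g, failing))
    return sets, lethal


def candidate_recovery_rate(config: SimConfig, margin: int = 2000):
    """Fraction of gene-resolved allelic sets whose planted causal mutations
    are recovered as the only candidates (per-line filtering)."""
    bundle = simulate_screen(config)
    rng = np.random.default_rng([config.seed, 977])
    sets, lethal = gene_resolved_sets(bundle, config, rng)
    tables = simulate_variant_tables(bundle.population, seed=config.seed)
    catalog = bundle.population.catalog

    n_ok = 0
    for gene, members in sets:
        s, e = catalog.interval(gene)
        interval = ("2", max(1, s - margin), min(config.chromosome_length, e + margin))
        nonallelic = {l: tables[l] for l in tables if l not in members}
        report = filter_candidates(
            tables, members, interval,
            nonallelic_variants=nonallelic, strict_shared=False,
        )
        expected_keys = set()
        for m in members:
            for mut in lethal[m].lethal_mutations:
                if mut.gene_id == gene:
                    for v in tables[m]:
                        if v.pos == mut.position and v.impact == "HIGH":
                            expected_keys.add(v.key())
        got = {v.key() for v in report.candidates}
        n_ok += got == expected_keys and len(got) > 0
    return n_ok, len(sets)
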