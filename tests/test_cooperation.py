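"""Eq.-2 production calls, evidence gates and network assembly."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from strainteract import (
    AMINO_ACIDS,
    CooperationEdge,
    ProductionCall,
    assemble_network,
    infer_cooperation,
    infer_network,
    relative_production,
    transcription_support,
)
from strainteract.cooperation import production_calls
from strainteract.simulate import (
    SimConfig,
    default_production_roles,
    gen_amino_profiles,
    gen_pathway_map,
    representatives,
)
from strainteract.classify import roman_label


def profile_from_reps(focal, medium, aa, day0, day8):
    rows = []
    for day, reps in ((0, day0), (8, day8)):
        for r, c in enumerate(reps, start=1):
            rows.append(
                {
                    "focal_group": focal, "medium_source": medium, "amino_acid": aa,
                    "day": day, "replicate": r, "concentration": c,
                }
            )
    return pd.DataFrame(rows)


class TestRelativeProduction:
    def test_doubling_is_called_produced(self):
        prof = profile_from_reps("ANI_I", "ANI_II", "methionine", [1, 1, 1, 1], [2, 2, 2, 2])
        call = relative_production(prof, "ANI_I", "ANI_II", "methionine")
        assert call.ratio == pytest.approx(2.0)
        assert call.call == "produced"

    def test_unchanged_concentrations_are_neutral(self):
        prof = profile_from_reps("ANI_I", "ANI_II", "glycine", [1, 2, 3, 4], [1, 2, 3, 4])
        call = relative_production(prof, "ANI_I", "ANI_II", "glycine")
        assert call.ratio == pytest.approx(1.0)
        assert call.p == pytest.approx(1.0)
        assert call.call == "neutral"

    def test_halving_is_called_utilised_with_hand_welch_oracle(self):
        day0 = [1.0, 1.05, 0.95, 1.0]
        day8 = [0.5, 0.55, 0.45, 0.5]
        prof = profile_from_reps("ANI_II", "ANI_I", "histidine", day0, day8)
        call = relative_production(prof, "ANI_II", "ANI_I", "histidine")
        assert call.ratio == pytest.approx(0.5)
        assert call.call == "utilised"
        # explicit Welch arithmetic, independent of the implementation path
        va = np.var(day8, ddof=1)
        vb = np.var(day0, ddof=1)
        t_hand = (np.mean(day8) - np.mean(day0)) / math.sqrt(va / 4 + vb / 4)
        assert t_hand == pytest.approx(-17.32, abs=0.01)
        assert call.p < 0.05

    def test_ratio_versus_one_mode_available(self):
        prof = profile_from_reps("ANI_I", "ANI_II", "serine", [1, 1, 1, 1], [2.0, 2.1, 1.9, 2.0])
        call = relative_production(prof, "ANI_I", "ANI_II", "serine", test="ratios")
        assert call.call == "produced"

    def test_zero_day0_mean_rejected(self):
        prof = profile_from_reps("ANI_I", "ANI_II", "serine", [0, 0, 0, 0], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="zero"):
            relative_production(prof, "ANI_I", "ANI_II", "serine")

    def test_missing_replicates_rejected(self):
        prof = profile_from_reps("ANI_I", "ANI_II", "serine", [1.0], [1.0])
        with pytest.raises(ValueError, match="replicates"):
            relative_production(prof, "ANI_I", "ANI_II", "serine")

    def test_unknown_amino_acid_rejected(self):
        prof = profile_from_reps("ANI_I", "ANI_II", "serine", [1, 1], [1, 1])
        with pytest.raises(ValueError, match="unknown amino acid"):
            relative_production(prof, "ANI_I", "ANI_II", "ornithine")

    def test_call_partition_is_exhaustive_and_exclusive(self, study):
        calls = production_calls(study["amino"])
        for c in calls:
            matches = [
                c.call == "produced" and (c.ratio > 1 and c.p < 0.05),
                c.call == "utilised" and (c.ratio < 1 and c.p < 0.05),
                c.call == "neutral" and not (c.p < 0.05 and c.ratio != 1),
            ]
            assert sum(bool(m) for m in matches) == 1, c


class TestTranscriptionSupport:
    @pytest.fixture
    def pathway(self):
        return {("i1", aa): f"i1|{aa}_terminal" for aa in AMINO_ACIDS}

    def make_records(self, fc, padj):
        return pd.DataFrame(
            [{
                "isolate": "i1", "gene": "i1|methionine_terminal",
                "condition": "vs_ANI_II", "log2_fold_change": fc, "p_adjusted": padj,
            }]
        )

    @pytest.mark.parametrize(
        "fc,padj,expected",
        [
            (3.0, 0.001, True),
            (0.9, 0.001, False),   # fold-change gate: log2FC must exceed 1
            (-2.5, 0.001, False),  # direction must be up, magnitude not enough
            (1.5, 0.06, False),    # adjusted-p gate
        ],
    )
    def test_gates(self, pathway, fc, padj, expected):
        ok, _ = transcription_support(
            self.make_records(fc, padj), pathway, ["i1"], "vs_ANI_II", "methionine"
        )
        assert ok is expected

    def test_strict_aggregation_requires_every_isolate(self, pathway):
        pathway = dict(pathway)
        pathway[("i2", "methionine")] = "i2|methionine_terminal"
        rec = pd.concat(
            [
                self.make_records(3.0, 0.001),
                pd.DataFrame([{
                    "isolate": "i2", "gene": "i2|methionine_terminal",
                    "condition": "vs_ANI_II", "log2_fold_change": 0.2, "p_adjusted": 0.5,
                }]),
            ]
        )
        strict, _ = transcription_support(rec, pathway, ["i1", "i2"], "vs_ANI_II", "methionine")
        loose, _ = transcription_support(
            rec, pathway, ["i1", "i2"], "vs_ANI_II", "methionine", aggregation="any"
        )
        assert strict is False and loose is True

    def test_unmapped_pathway_entry_rejected(self, pathway):
        with pytest.raises(KeyError, match="terminal gene"):
            transcription_support(
                self.make_records(3.0, 0.001), {}, ["i1"], "vs_ANI_II", "methionine"
            )


def calls_for_pair(focal, medium, produced=(), utilised=()):
    """Full 18-amino-acid call set for one conditioned-medium condition."""
    out = []
    for aa in AMINO_ACIDS:
        if aa in produced:
            ratio, p, call = 2.0, 0.01, "produced"
        elif aa in utilised:
            ratio, p, call = 0.5, 0.01, "utilised"
        else:
            ratio, p, call = 1.0, 0.6, "neutral"
        out.append(ProductionCall(focal, medium, aa, ratio, p, call))
    return out


# Evidence sets from the two reciprocal conditioned-medium experiments
# between the first two genotypic groups.
I_PRODUCES = ("methionine", "leucine", "histidine", "tryptophan")
I_UPREGULATED = ("methionine", "glutamine", "threonine", "aspartate",
                 "histidine", "tryptophan", "lysine", "arginine")
II_UTILISES = ("methionine", "aspartate", "histidine", "tryptophan",
               "tyrosine", "proline", "arginine")
II_PRODUCES = ("alanine", "glutamine", "phenylalanine", "glycine", "threonine")
II_UPREGULATED = ("alanine", "phenylalanine", "glycine", "threonine",
                  "glutamate", "tyrosine")
I_UTILISES = ("glutamine", "phenylalanine", "glycine", "threonine",
              "isoleucine", "tyrosine", "proline", "arginine")


class TestInferCooperation:
    def evidence(self, upregulated):
        return {aa: (3.0, 0.001) for aa in upregulated}

    def test_reproduces_forward_worked_example(self):
        """I -> II cooperation reduces to exactly Met/His/Trp; Leu drops out."""
        calls = calls_for_pair("ANI_I", "ANI_II", produced=I_PRODUCES) + calls_for_pair(
            "ANI_II", "ANI_I", utilised=II_UTILISES
        )
        edges = infer_cooperation(calls, self.evidence(I_UPREGULATED), ("ANI_I", "ANI_II"))
        assert {e.amino_acid for e in edges} == {"methionine", "histidine", "tryptophan"}

    def test_reproduces_reverse_worked_example(self):
        """II -> I reduces to Phe/Gly/Thr; Gln (no upregulation) and Ala
        (not utilised) are excluded purely by the conjunction."""
        calls = calls_for_pair("ANI_II", "ANI_I", produced=II_PRODUCES) + calls_for_pair(
            "ANI_I", "ANI_II", utilised=I_UTILISES
        )
        edges = infer_cooperation(calls, self.evidence(II_UPREGULATED), ("ANI_II", "ANI_I"))
        assert {e.amino_acid for e in edges} == {"phenylalanine", "glycine", "threonine"}

    def test_all_neutral_calls_yield_no_edges(self):
        calls = calls_for_pair("ANI_I", "ANI_II") + calls_for_pair("ANI_II", "ANI_I")
        assert infer_cooperation(calls, self.evidence(AMINO_ACIDS), ("ANI_I", "ANI_II")) == []

    def test_missing_reciprocal_call_rejected(self):
        calls = calls_for_pair("ANI_I", "ANI_II", produced=("methionine",))
        with pytest.raises(ValueError, match="reciprocal"):
            infer_cooperation(calls, self.evidence(AMINO_ACIDS), ("ANI_I", "ANI_II"))

    def test_dropping_any_gate_only_grows_the_edge_set(self):
        """The three-way conjunction is monotone: each gate only filters."""
        calls = calls_for_pair("ANI_I", "ANI_II", produced=I_PRODUCES) + calls_for_pair(
            "ANI_II", "ANI_I", utilised=II_UTILISES
        )
        full = {e.amino_acid for e in
                infer_cooperation(calls, self.evidence(I_UPREGULATED), ("ANI_I", "ANI_II"))}
        no_tx_gate = {e.amino_acid for e in
                      infer_cooperation(calls, self.evidence(AMINO_ACIDS), ("ANI_I", "ANI_II"))}
        no_util_gate_calls = calls_for_pair("ANI_I", "ANI_II", produced=I_PRODUCES) + \
            calls_for_pair("ANI_II", "ANI_I", utilised=AMINO_ACIDS)
        no_util_gate = {e.amino_acid for e in
                        infer_cooperation(no_util_gate_calls, self.evidence(I_UPREGULATED),
                                          ("ANI_I", "ANI_II"))}
        assert full <= no_tx_gate
        assert full <= no_util_gate
        assert no_tx_gate <= set(I_PRODUCES)


class TestAssembleNetwork:
    SIX_PAIR_SETS = {
        ("ANI_I", "ANI_II"): ("methionine", "histidine", "tryptophan"),
        ("ANI_II", "ANI_I"): ("phenylalanine", "glycine", "threonine"),
        ("ANI_I", "ANI_III"): ("methionine", "histidine"),
        ("ANI_III", "ANI_I"): ("phenylalanine", "cysteine"),
        ("ANI_II", "ANI_III"): ("glutamate", "proline"),
        ("ANI_III", "ANI_II"): ("glutamine", "cysteine", "tyrosine"),
    }

    @staticmethod
    def edge(producer, consumer, aa):
        return CooperationEdge(producer, consumer, aa, 2.0, 0.01, 0.5, 0.01, 3.0, 0.001)

    def test_six_pair_scheme_covers_eleven_amino_acids(self):
        edges = [
            self.edge(x, y, aa) for (x, y), aas in self.SIX_PAIR_SETS.items() for aa in aas
        ]
        _, summary = assemble_network(edges)
        assert summary["n_amino_acids"] == 11
        assert summary["n_edges"] == 15

    def test_single_edge_summary(self):
        g, summary = assemble_network([self.edge("ANI_I", "ANI_II", "methionine")])
        assert summary["n_amino_acids"] == 1
        assert summary["out_degree"] == {"ANI_I": 1, "ANI_II": 0}
        assert summary["in_degree"] == {"ANI_I": 0, "ANI_II": 1}

    def test_distinct_count_matches_set_union_oracle(self):
        rng = np.random.default_rng(7)
        pairs = list(self.SIX_PAIR_SETS)
        for _ in range(25):
            chosen = [
                (pairs[int(rng.integers(len(pairs)))], AMINO_ACIDS[int(rng.integers(18))])
                for _ in range(int(rng.integers(1, 12)))
            ]
            chosen = list(dict.fromkeys(((x, y, aa) for (x, y), aa in chosen)))
            edges = [self.edge(x, y, aa) for x, y, aa in chosen]
            _, summary = assemble_network(edges)
            assert summary["n_amino_acids"] == len({aa for _, _, aa in chosen})

    def test_duplicate_edge_rejected(self):
        e = self.edge("ANI_I", "ANI_II", "methionine")
        with pytest.raises(ValueError, match="duplicate"):
            assemble_network([e, e])


class TestFullNetworkRecovery:
    def test_zero_noise_recovery_is_exact(self):
        cfg = SimConfig(seed=5, concentration_noise_cv=0.0)
        amino, tx = gen_amino_profiles(cfg)
        pwy = {(r.isolate, r.amino_acid): r.gene for r in gen_pathway_map(cfg).itertuples()}
        edges = infer_network(amino, tx, pwy, representatives(cfg))
        got = {(e.producer, e.consumer, e.amino_acid) for e in edges}
        planted = {
            (roman_label(x), roman_label(y), aa) for x, y, aa in default_production_roles()
        }
        assert got == planted

    def test_no_planted_roles_yields_empty_network(self):
        cfg = SimConfig(seed=5, production_roles=frozenset(), concentration_noise_cv=0.0)
        amino, tx = gen_amino_profiles(cfg)
        pwy = {(r.isolate, r.amino_acid): r.gene for r in gen_pathway_map(cfg).itertuples()}
        assert infer_network(amino, tx, pwy, representatives(cfg)) == []

    def test_inferred_edges_subset_of_production_only(self, study):
        """Adding gates can only shrink the edge set."""
        amino, tx = study["amino"], study["transcription"]
        pwy = {(r.isolate, r.amino_acid): r.gene
               for r in study["pathway"].itertuples()}
        edges = infer_network(amino, tx, pwy, representatives(study["config"]))
        produced = {
            (c.focal_group, c.medium_source, c.amino_acid)
            for c in production_calls(amino)
            if c.call == "produced"
        }
        for e in edges:
            assert (e.producer, e.consumer, e.amino_acid) in produced
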