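import numpy as np
import pytest

from markermine.io_formats import Read
from markermine.homolog_resolution import (
    MappingParams,
    make_nt_aligner,
    map_reads,
    split_hao_hdh,
    split_narG_nxrA,
)
from markermine.synthetic_data import back_translate, mutate_protein, random_protein
from oracles import sw_nt_score


def _random_nt(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestMappingParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mismatch_penalty": 0},
            {"indel_penalty": 0},
            {"min_identity": 0.0},
            {"min_identity": 101.0},
            {"min_read_coverage": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MappingParams(**kwargs)


class TestMapReads:
    def test_exact_fragment_maps_fully(self, rng):
        ref = _random_nt(rng, 1200)
        read = Read(id="r", seq=ref[300:450])
        mapped, unmapped, details = map_reads([read], {"ref": ref})
        assert [r.id for r in mapped] == ["r"]
        assert details["r"].identity == 100.0
        assert details["r"].read_coverage == 100.0

    def test_reverse_strand_fragment_maps(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        ref = _random_nt(rng, 800)
        read = Read(id="r", seq=ref[100:260].translate(comp)[::-1])
        mapped, _, details = map_reads([read], {"ref": ref})
        assert mapped and details["r"].strand == "-"

    def test_mostly_randomized_reads_do_not_map(self, rng):
        # 60% of bases randomized: beyond the 50/50 criterion in >=99% of reads
        ref = _random_nt(rng, 1000)
        reads = []
        for i in range(300):
            frag = list(ref[200:380])
            for j in rng.choice(len(frag), size=int(0.6 * len(frag)), replace=False):
                frag[j] = "ACGT"[rng.integers(4)]
            reads.append(Read(id=f"r{i}", seq="".join(frag)))
        mapped, unmapped, _ = map_reads(reads, {"ref": ref})
        assert len(mapped) <= 3

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        ref = _random_nt(rng, 600)
        reads = [Read(id=f"r{i}", seq=_random_nt(rng, 150)) for i in range(20)]
        reads.append(Read(id="hit", seq=ref[10:160]))
        mapped, unmapped, _ = map_reads(reads, {"ref": ref})
        assert len(mapped) + len(unmapped) == len(reads)
        assert {r.id for r in mapped}.isdisjoint({r.id for r in unmapped})

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            map_reads([Read(id="r", seq="ACGT")], {})

    def test_aligner_scores_match_bruteforce(self, rng):
        # the internal nucleotide scorer against a naive DP on small pairs
        params = MappingParams()
        aligner = make_nt_aligner(params)
        for _ in range(20):
            a = _random_nt(rng, int(rng.integers(40, 300)))
            b = _random_nt(rng, int(rng.integers(40, 300)))
            if rng.random() < 0.5:
                b = b[:100] + a[: int(rng.integers(20, len(a)))] + b[100:]
            assert aligner.score(a, b) == pytest.approx(
                sw_nt_score(a, b, mismatch=2.0, gap=3.0)
            )


def _fragment_reads(rng, nt, n, length=150, prefix="r"):
    reads = []
    for i in range(n):
        start = int(rng.integers(0, len(nt) - length + 1))
        reads.append(Read(id=f"{prefix}{i}", seq=nt[start : start + length]))
    return reads


class TestSplitHaoHdh:
    def test_split_separates_the_homolog_pair(self, rng):
        hdh_aa = random_protein(520, rng)
        hao_aa = mutate_protein(hdh_aa, 0.45, rng)  # ~55% AA identity
        hdh_nt = back_translate(hdh_aa, rng)
        hao_nt = back_translate(hao_aa, rng)  # silent sites independent
        hdh_reads = _fragment_reads(rng, hdh_nt, 25, prefix="hdh")
        hao_reads = _fragment_reads(rng, hao_nt, 25, prefix="hao")
        split = split_hao_hdh(hdh_reads + hao_reads, {"hdh_1": hdh_nt})
        assert len(split["hdh"]) + len(split["hao"]) == 50
        hdh_ids = {r.id for r in split["hdh"]}
        assert sum(r.id.startswith("hdh") for r in split["hdh"]) >= 24
        assert sum(r.id.startswith("hao") for r in split["hao"]) >= 24
        assert hdh_ids.isdisjoint({r.id for r in split["hao"]})


class TestSplitNarGNxrA:
    def _world(self, rng):
        narg_anc = random_protein(600, rng)
        nxra_anc = mutate_protein(narg_anc, 0.35, rng)
        subset_a = {"nxrA_A_1": mutate_protein(nxra_anc, 0.15, rng)}
        subset_b = {"nxrA_B_1": mutate_protein(nxra_anc, 0.15, rng)}
        return narg_anc, subset_a, subset_b

    def test_three_way_partition_recovers_origins(self, rng):
        from markermine.homology_search import search_reads

        narg, subset_a, subset_b = self._world(rng)
        narg_nt = back_translate(narg, rng)
        nxa_nt = back_translate(subset_a["nxrA_A_1"], rng)
        nxb_nt = back_translate(subset_b["nxrA_B_1"], rng)
        reads = (
            _fragment_reads(rng, narg_nt, 15, prefix="narg")
            + _fragment_reads(rng, nxa_nt, 15, prefix="nxa")
            + _fragment_reads(rng, nxb_nt, 15, prefix="nxb")
        )
        # first-round custom db: the combined narG/nxrA set
        custom = {"narG_1": narg, **subset_a, **subset_b}
        res = search_reads(reads, custom)
        orig = {rid: res.best(rid).bit_score for rid in res.hits}
        split = split_narG_nxrA(
            [r for r in reads if r.id in orig], orig, subset_a, subset_b
        )
        total = sum(len(v) for v in split.values())
        assert total == len(orig)
        assert sum(r.id.startswith("nxa") for r in split["nxrA_A"]) >= 13
        assert sum(r.id.startswith("nxb") for r in split["nxrA_B"]) >= 13
        assert sum(r.id.startswith("narg") for r in split["narG"]) >= 13

    def test_missing_original_score_is_an_error(self, rng):
        _, subset_a, subset_b = self._world(rng)
        read = Read(id="r", seq="ACGT" * 40)
        with pytest.raises(KeyError, match="original custom score"):
            split_narG_nxrA([read], {}, subset_a, subset_b)
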