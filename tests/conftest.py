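import pytest

from cosegscore.fixtures import EXAMPLE_IDS, build_example


@pytest.fixture(params=EXAMPLE_IDS)
def worked_example(request):
    return build_example(request.param)


def assert_matches_expected(example, result):
    """Assert a result reproduces the example's expected per-variant values."""
    assert sorted(result.excluded_loci) == sorted(example.expected_excluded_loci)
    assert set(result.variants) == set(example.expected)
    for vid, exp in example.expected.items():
        ev = result.variants[vid]
        for key, want in exp.items():
            got = getattr(ev, key)
            if isinstance(want, dict):
                assert got is not None, f"{example.example_id}/{vid}: missing {key}"
                for subkey, subwant in want.items():
                    assert got[subkey] == pytest.approx(subwant), (
                        f"{example.example_id}/{vid}: {key}.{subkey}"
                    )
            elif isinstance(want, float):
                assert got == pytest.approx(want), f"{example.example_id}/{vid}: {key}"
            else:
                assert got == want, f"{example.example_id}/{vid}: {key}"
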