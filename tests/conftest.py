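import pytest

from nmrbind.peaklist import PeakList, Resonance
from nmrbind.synthetic import ThreeStateStudySpec, generate_three_state_study


def make_peaklist(shifts, state_label="state", field_MHz=800.0):
    """Build a PeakList from {residue_index: (shift_H, shift_N)}."""
    pl = PeakList(state_label=state_label, field_MHz=field_MHz)
    for idx, (h, n) in shifts.items():
        pl.add(Resonance(idx, f"A{idx}", shift_N=n, shift_H=h))
    return pl


@pytest.fixture(scope="session")
def three_state_study():
    """Default-noise planted study shared across integration tests."""
    return generate_three_state_study(ThreeStateStudySpec(n_residues=24, seed=11))


@pytest.fixture
def sparky_file(tmp_path):
    def write(text, name="peaks.list"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
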