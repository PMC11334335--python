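import logging

import pytest

from morallex.pipeline import StudyResult, run_synthetic_study
from morallex.synthetic_data import GeneratorConfig

logging.getLogger("morallex").setLevel(logging.ERROR)


CHA_FIXTURE = """\
@UTF8
@Begin
@Languages:\teng
@Participants:\tCHI Sarah Target_Child, MOT Mary Mother
@ID:\teng|TestCorpus|CHI|2;06.00|female|||Target_Child|||
@ID:\teng|TestCorpus|MOT|||||Mother|||
*CHI:\thelp me .
*CHI:\tthat is not fair .
*MOT:\tlet me help you up .
*MOT:\tbe gentle with the puppy .
*MOT:\tdo you want juice ?
%mor:\tpro|do pro|you v|want n|juice ?
@End
"""


@pytest.fixture
def cha_file(tmp_path):
    path = tmp_path / "testcorpus.cha"
    path.write_text(CHA_FIXTURE)
    return path


DIC_FIXTURE = """\
%
1\tcare.virtue
2\tcare.vice
3\tfairness.virtue
4\tfairness.vice
5\tloyalty.virtue
6\tloyalty.vice
7\tauthority.virtue
8\tauthority.vice
9\tpurity.virtue
10\tpurity.vice
%
help*\t1
hurt\t2
fair\t3
cheat*\t4
together\t5
enemy\t6
obey\t7
disobey\t8
clean\t9
dirty\t10
"""


@pytest.fixture
def dic_file(tmp_path):
    path = tmp_path / "mfd_toy.dic"
    path.write_text(DIC_FIXTURE)
    return path


@pytest.fixture(scope="session")
def small_study() -> StudyResult:
    """One full pipeline run on a small corpus, shared across tests."""
    config = GeneratorConfig(seed=11, sentences_per_age_role=150)
    return run_synthetic_study(config)
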