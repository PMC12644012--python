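"""szpipe: EEG seizure detection with DWT sub-band features, two-stage
class balancing, and a CSAE-GRU classifier.

Typical use::

    from szpipe import synthdata, pipeline_eval
    segs = synthdata.gen_dataset(synthdata.SynthConfig(seed=1))
    table = features.build_feature_table(segs)
    report = pipeline_eval.kfold_cross_validate(
        table, k=5, runner=pipeline_eval.make_default_runner(), seed=1)
"""

from . import balancing, features, model, pipeline_eval, signal_io, synthdata
from .balancing import BalanceConfig, two_stage_balance
from .features import (FeatureTable, FuzzyEnSpec, apply_normalizer,
                       build_feature_table, fit_normalizer)
from .model import (CSAE, ClassifierConfig, CsaeConfig, ModelBundle,
                    build_classifier, predict, predict_proba, pretrain_csae,
                    train_classifier)
from .pipeline_eval import (EvalReport, kfold_cross_validate,
                            make_default_runner, roc_auc, run_pipeline,
                            stratified_split)
from .signal_io import (EegSegment, FilterSpec, SeizureAnnotation,
                        bandpass_filter, extract_ictal_windows,
                        extract_interictal_epochs, read_bonn_segment,
                        read_edf_recording)
from .synthdata import SynthConfig, gen_dataset

__version__ = "0.1.0"
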