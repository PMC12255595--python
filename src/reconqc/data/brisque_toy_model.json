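{
 "version": 1,
 "feature_means": [
  0.5042500000000003,
  0.02167516370922433,
  10.000000000000002,
  0.032509554795012406,
  0.00020909354356181864,
  0.002741924345974631,
  10.000000000000002,
  0.032804079145897995,
  0.00020027397574612265,
  0.0027445013615848926,
  10.000000000000002,
  0.017873745926063063,
  0.0006440206482943061,
  0.0021323527458280336,
  10.000000000000002,
  0.01738380587183784,
  0.0006668900925396143,
  0.00212282779148027,
  0.5581250000000002,
  0.04633230449137524,
  10.000000000000002,
  0.016687042821106387,
  0.004876596320615765,
  0.007905445528654863,
  10.000000000000002,
  0.016775111634492607,
  0.004849207538011776,
  0.007896386094584042,
  10.000000000000002,
  -0.02733224120822923,
  0.01080666794270816,
  0.005100188352724193,
  10.000000000000002,
  -0.027907188141215986,
  0.010874061819759166,
  0.005073832434935618
 ],
 "feature_scales": [
  0.047484780170346054,
  0.0028495591460630494,
  1e-06,
  0.003045045643708954,
  3.83823819218611e-05,
  0.00046843977611282485,
  1e-06,
  0.0029926632540367647,
  4.021902513130283e-05,
  0.0004672169674822907,
  1e-06,
  0.002101741596816273,
  0.00012618037296817993,
  0.00034403472997545287,
  1e-06,
  0.0020963774649553598,
  0.00012403480317185547,
  0.00035389667595123555,
  0.05712481566900148,
  0.0066021006793706045,
  1e-06,
  0.004706102403010548,
  0.0014253797610956625,
  0.0014949586353411742,
  1e-06,
  0.004867472904124112,
  0.0013418700417589953,
  0.0014908516459799692,
  1e-06,
  0.009250126442557103,
  0.0030561580047426193,
  0.0008191082473299886,
  1e-06,
  0.007666071698135278,
  0.0028744118130357766,
  0.0008673617367461622
 ],
 "weights": [
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0
 ],
 "provenance": "toy model: 24 clean synthetic phantoms, seed 20240101"
}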