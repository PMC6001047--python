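cancer_type	signature
Colorectal	Signature_1
Colorectal	Signature_5
Colorectal	Signature_6
Colorectal	Signature_10
Colorectal	Signature_15
Colorectal	Signature_20
Breast	Signature_1
Breast	Signature_2
Breast	Signature_3
Breast	Signature_5
Breast	Signature_8
Breast	Signature_13
Lung	Signature_1
Lung	Signature_2
Lung	Signature_4
Lung	Signature_5
Lung	Signature_13
Melanoma	Signature_1
Melanoma	Signature_5
Melanoma	Signature_7
Melanoma	Signature_11
Ovarian	Signature_1
Ovarian	Signature_3
Ovarian	Signature_5
Liver	Signature_1
Liver	Signature_4
Liver	Signature_5
Liver	Signature_6
Liver	Signature_12
Liver	Signature_16
Liver	Signature_17
Liver	Signature_22
Liver	Signature_23
Liver	Signature_24
Stomach	Signature_1
Stomach	Signature_2
Stomach	Signature_15
Stomach	Signature_17
Stomach	Signature_20
Stomach	Signature_21
Leukemia	Signature_1
Leukemia	Signature_2
Leukemia	Signature_5
Leukemia	Signature_9
Leukemia	Signature_13
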