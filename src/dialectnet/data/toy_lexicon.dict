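;;; Toy pronunciation dictionary in CMU-dict text format.
;;; Hand-written entries for the words used in the worked examples.
BATH  B AE1 TH
BEST  B EH1 S T
COAL  K OW1 L
COLD  K OW1 L D
COLD(2)  K UH1 L D
DRANK  D R AE1 NG K
FLOOR  F L AO1 R
PIN  P IH1 N
PLATE  P L EY1 T
POUND  P AW1 N D
TEND  T EH1 N D
THIRD  TH ER1 D
THIS  DH IH1 S
TOLD  T OW1 L D
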