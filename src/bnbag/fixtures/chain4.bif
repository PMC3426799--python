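network chain4 {
}
variable X0 {
  type discrete [ 2 ] { s0, s1 };
}
variable X1 {
  type discrete [ 2 ] { s0, s1 };
}
variable X2 {
  type discrete [ 2 ] { s0, s1 };
}
variable X3 {
  type discrete [ 2 ] { s0, s1 };
}
probability ( X0 ) {
  table 0.5, 0.5;
}
probability ( X1 | X0 ) {
  (s0) 0.9, 0.09999999999999998;
  (s1) 0.09999999999999998, 0.9;
}
probability ( X2 | X1 ) {
  (s0) 0.9, 0.09999999999999998;
  (s1) 0.09999999999999998, 0.9;
}
probability ( X3 | X2 ) {
  (s0) 0.9, 0.09999999999999998;
  (s1) 0.09999999999999998, 0.9;
}
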