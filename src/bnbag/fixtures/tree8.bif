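network tree8 {
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
variable X4 {
  type discrete [ 2 ] { s0, s1 };
}
variable X5 {
  type discrete [ 2 ] { s0, s1 };
}
variable X6 {
  type discrete [ 2 ] { s0, s1 };
}
variable X7 {
  type discrete [ 2 ] { s0, s1 };
}
probability ( X0 ) {
  table 0.5, 0.5;
}
probability ( X1 | X0 ) {
  (s0) 0.85, 0.15000000000000002;
  (s1) 0.15000000000000002, 0.85;
}
probability ( X2 | X0 ) {
  (s0) 0.85, 0.15000000000000002;
  (s1) 0.15000000000000002, 0.85;
}
probability ( X3 | X1 ) {
  (s0) 0.85, 0.15000000000000002;
  (s1) 0.15000000000000002, 0.85;
}
probability ( X4 | X1 ) {
  (s0) 0.85, 0.15000000000000002;
  (s1) 0.15000000000000002, 0.85;
}
probability ( X5 | X2 ) {
  (s0) 0.85, 0.15000000000000002;
  (s1) 0.15000000000000002, 0.85;
}
probability ( X6 | X2 ) {
  (s0) 0.85, 0.15000000000000002;
  (s1) 0.15000000000000002, 0.85;
}
probability ( X7 | X3 ) {
  (s0) 0.85, 0.15000000000000002;
  (s1) 0.15000000000000002, 0.85;
}
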