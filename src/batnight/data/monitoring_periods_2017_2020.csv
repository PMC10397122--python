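location_id,start_date,end_date
A,2018-02-28,2018-12-31
A,2019-01-01,2019-12-31
A,2020-06-21,2020-07-27
A,2020-09-10,2020-09-19
B,2017-08-02,2017-12-26
B,2018-03-01,2018-12-31
B,2019-01-01,2019-12-31
B,2020-01-01,2020-09-30
C,2018-03-06,2018-12-31
C,2019-01-01,2019-12-31
C,2020-02-18,2020-05-17
C,2020-07-30,2020-09-25
D,2017-09-27,2017-12-31
D,2018-03-06,2018-11-18
D,2019-05-09,2019-12-31
D,2020-06-24,2020-10-30
E,2019-02-25,2019-06-27
E,2019-07-11,2019-12-31
E,2020-02-15,2020-06-06
E,2020-07-23,2020-12-31
F,2018-04-04,2018-07-18
F,2018-08-15,2018-12-31
F,2019-01-01,2019-12-31
F,2020-04-06,2020-06-12
F,2020-08-04,2020-09-03
G,2018-11-15,2018-12-31
G,2019-01-01,2019-12-31
G,2020-01-01,2020-06-08
G,2020-06-25,2020-07-07
G,2020-07-26,2020-11-16
H,2017-08-02,2017-12-31
H,2018-01-13,2018-12-31
H,2019-01-01,2019-10-18
H,2019-11-22,2019-12-31
H,2020-01-01,2020-02-07
H,2020-03-04,2020-12-31
I,2017-10-31,2017-12-31
I,2018-03-11,2018-12-21
I,2019-01-01,2019-12-31
I,2020-01-01,2020-06-04
I,2020-07-13,2020-12-31
J,2018-09-11,2018-12-31
J,2019-01-01,2019-12-31
J,2020-01-01,2020-12-31
K,2019-01-01,2019-08-22
K,2019-09-19,2019-09-27
K,2019-12-01,2019-12-31
K,2020-08-04,2020-12-16
L,2017-07-26,2017-12-11
L,2018-01-24,2018-12-31
L,2019-01-01,2019-12-31
L,2020-03-18,2020-05-31
L,2020-09-22,2020-11-09
M,2017-08-18,2017-12-31
M,2018-01-01,2018-12-31
M,2019-01-01,2019-12-31
M,2020-03-21,2020-04-08
M,2020-09-23,2020-11-13
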