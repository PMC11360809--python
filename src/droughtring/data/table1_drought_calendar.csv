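site,year,month,severity
Dorna Candrenilor,1972,3,severe
Dorna Candrenilor,1973,1,severe
Dorna Candrenilor,1974,2,severe
Dorna Candrenilor,1974,3,severe
Dorna Candrenilor,1974,4,extreme
Dorna Candrenilor,1975,3,severe
Dorna Candrenilor,1982,11,severe
Dorna Candrenilor,1983,12,severe
Dorna Candrenilor,1986,5,severe
Dorna Candrenilor,1986,11,severe
Dorna Candrenilor,1989,3,severe
Dorna Candrenilor,1990,2,severe
Dorna Candrenilor,1990,3,severe
Dorna Candrenilor,1994,7,severe
Dorna Candrenilor,2000,6,extreme
Dorna Candrenilor,2000,12,extreme
Dorna Candrenilor,2001,1,severe
Dorna Candrenilor,2002,2,severe
Dorna Candrenilor,2002,5,severe
Dorna Candrenilor,2002,6,severe
Dorna Candrenilor,2003,5,severe
Dorna Candrenilor,2003,6,extreme
Dorna Candrenilor,2007,6,severe
Dorna Candrenilor,2009,5,severe
Dorna Candrenilor,2009,9,severe
Dorna Candrenilor,2011,10,severe
Dorna Candrenilor,2011,11,severe
Dorna Candrenilor,2012,8,severe
Dorna Candrenilor,2012,9,severe
Dorna Candrenilor,2013,12,severe
Dorna Candrenilor,2015,7,severe
Dorna Candrenilor,2015,8,severe
Dorna Candrenilor,2015,9,severe
Dorna Candrenilor,2018,5,severe
Dorna Candrenilor,2018,10,extreme
Dorna Candrenilor,2019,8,severe
Dorna Candrenilor,2019,9,severe
Dorna Candrenilor,2019,10,severe
Dorna Candrenilor,2019,11,severe
Dorna Candrenilor,2019,12,severe
Dorna Candrenilor,2020,1,extreme
Turda,1972,3,severe
Turda,1973,1,severe
Turda,1973,2,severe
Turda,1974,2,severe
Turda,1974,3,severe
Turda,1974,4,extreme
Turda,1975,3,severe
Turda,1982,11,severe
Turda,1983,12,severe
Turda,1986,11,severe
Turda,1989,3,severe
Turda,1990,5,severe
Turda,1992,5,severe
Turda,1992,9,severe
Turda,1994,7,severe
Turda,2000,6,extreme
Turda,2000,7,severe
Turda,2000,8,severe
Turda,2000,10,severe
Turda,2000,11,severe
Turda,2000,12,extreme
Turda,2002,2,severe
Turda,2002,5,severe
Turda,2002,6,severe
Turda,2003,5,severe
Turda,2003,6,extreme
Turda,2006,12,severe
Turda,2008,2,severe
Turda,2009,5,severe
Turda,2011,10,severe
Turda,2011,11,severe
Turda,2012,8,severe
Turda,2012,9,severe
Turda,2012,10,severe
Turda,2017,2,severe
Turda,2018,9,severe
Turda,2018,10,severe
Turda,2018,11,severe
Turda,2019,10,severe
Turda,2020,1,severe
Zarnesti,1972,3,severe
Zarnesti,1972,4,severe
Zarnesti,1974,2,severe
Zarnesti,1974,3,severe
Zarnesti,1974,4,severe
Zarnesti,1975,3,severe
Zarnesti,1977,12,severe
Zarnesti,1978,1,severe
Zarnesti,1982,11,severe
Zarnesti,1983,4,severe
Zarnesti,1986,5,severe
Zarnesti,1986,10,severe
Zarnesti,1989,3,severe
Zarnesti,1990,3,severe
Zarnesti,1992,9,severe
Zarnesti,1996,7,severe
Zarnesti,2000,6,severe
Zarnesti,2000,7,severe
Zarnesti,2000,8,severe
Zarnesti,2000,12,extreme
Zarnesti,2001,1,severe
Zarnesti,2002,2,severe
Zarnesti,2002,5,severe
Zarnesti,2002,6,severe
Zarnesti,2003,5,severe
Zarnesti,2003,6,extreme
Zarnesti,2003,7,extreme
Zarnesti,2003,8,severe
Zarnesti,2006,12,severe
Zarnesti,2007,6,severe
Zarnesti,2007,7,extreme
Zarnesti,2011,10,severe
Zarnesti,2011,11,severe
Zarnesti,2012,8,severe
Zarnesti,2012,9,severe
Zarnesti,2015,7,severe
Zarnesti,2018,5,severe
Zarnesti,2018,10,extreme
Zarnesti,2019,8,severe
Zarnesti,2019,9,severe
Zarnesti,2019,11,severe
Zarnesti,2019,12,severe
Zarnesti,2020,1,severe
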