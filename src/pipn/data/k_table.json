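{
"OOOOOOOOX": -0.3771,
"OOOOOOOXO": 0.894,
"OOOOOOOXX": 0.028,
"OOOOOOXOO": 0.3153,
"OOOOOOXOX": -0.4321,
"OOOOOOXXO": 1.1403,
"OOOOOOXXX": 0.5062,
"OOOOOXOOO": -0.1537,
"OOOOOXOOX": -0.8597,
"OOOOOXOXO": 0.741,
"OOOOOXOXX": 0.1819,
"OOOOOXXOO": 0.3809,
"OOOOOXXOX": -0.1421,
"OOOOOXXXO": 1.549,
"OOOOOXXXX": 1.0012,
"OOOOXOOOO": -0.5466,
"OOOOXOOOX": -1.2464,
"OOOOXOOXO": 0.3809,
"OOOOXOOXX": -0.1421,
"OOOOXOXOO": 0.0398,
"OOOOXOXOX": -0.453,
"OOOOXOXXO": 1.2476,
"OOOOXOXXX": 0.7582,
"OOOOXXOOO": -0.2631,
"OOOOXXOOX": -0.7524,
"OOOOXXOXO": 0.9538,
"OOOOXXOXX": 0.5044,
"OOOOXXXOO": 0.6811,
"OOOOXXXOX": 0.2522,
"OOOOXXXXO": 2.014,
"OOOOXXXXX": 1.4962,
"OOOXOOOO": -0.5466,
"OOOXOOOX": -1.2464,
"OOOXOOXO": 0.3809,
"OOOXOOXX": -0.1422,
"OOOXOXOO": 0.0398,
"OOOXOXOX": -0.4533,
"OOOXOXXO": 1.247,
"OOOXOXXX": 0.7559,
"OOOXXOOO": -0.2632,
"OOOXXOOX": -0.753,
"OOOXXOXO": 0.9524,
"OOOXXOXX": 0.5,
"OOOXXXOO": 0.6781,
"OOOXXXOX": 0.2441,
"OOOXXXXO": 2.0,
"OOOXXXXX": 1.4649,
"OOXOOOO": -0.5466,
"OOXOOOX": -1.2465,
"OOXOOXO": 0.3804,
"OOXOOXX": -0.1443,
"OOXOXOO": 0.0385,
"OOXOXOX": -0.458,
"OOXOXXO": 1.2373,
"OOXOXXX": 0.7323,
"OOXXOOO": -0.2661,
"OOXXOOX": -0.7627,
"OOXXOXO": 0.9346,
"OOXXOXX": 0.4629,
"OOXXXOO": 0.6481,
"OOXXXOX": 0.1872,
"OOXXXXO": 1.9169,
"OOXXXXX": 1.3291,
"OXOOOO": -0.547,
"OXOOOX": -1.2501,
"OXOOXO": 0.372,
"OXOOXX": -0.1687,
"OXOXOO": 0.0215,
"OXOXOX": -0.5,
"OXOXXO": 1.1687,
"OXOXXX": 0.6108,
"OXXOOO": -0.2959,
"OXXOOX": -0.8313,
"OXXOXO": 0.8313,
"OXXOXX": 0.2959,
"OXXXOO": 0.5,
"OXXXOX": -0.0431,
"OXXXXO": 1.6034,
"OXXXXX": 0.8931,
"XOOOOO": -0.8931,
"XOOOOX": -1.6034,
"XOOOXO": 0.0431,
"XOOOXX": -0.5,
"XOOXOO": -0.2959,
"XOOXOX": -0.8313,
"XOOXXO": 0.8313,
"XOOXXX": 0.2959,
"XOXOOO": -0.6108,
"XOXOOX": -1.1687,
"XOXOXO": 0.5,
"XOXOXX": -0.0215,
"XOXXOO": 0.1687,
"XOXXOX": -0.372,
"XOXXXO": 1.2501,
"XOXXXX": 0.547,
"XXOOOOO": -1.3291,
"XXOOOOX": -1.9169,
"XXOOOXO": -0.1872,
"XXOOOXX": -0.6481,
"XXOOXOO": -0.4629,
"XXOOXOX": -0.9346,
"XXOOXXO": 0.7627,
"XXOOXXX": 0.2661,
"XXOXOOO": -0.7323,
"XXOXOOX": -1.2373,
"XXOXOXO": 0.458,
"XXOXOXX": -0.0385,
"XXOXXOO": 0.1443,
"XXOXXOX": -0.3804,
"XXOXXXO": 1.2465,
"XXOXXXX": 0.5466,
"XXXOOOOO": -1.4649,
"XXXOOOOX": -2.0,
"XXXOOOXO": -0.2441,
"XXXOOOXX": -0.6781,
"XXXOOXOO": -0.5,
"XXXOOXOX": -0.9524,
"XXXOOXXO": 0.753,
"XXXOOXXX": 0.2632,
"XXXOXOOO": -0.7559,
"XXXOXOOX": -1.247,
"XXXOXOXO": 0.4533,
"XXXOXOXX": -0.0398,
"XXXOXXOO": 0.1422,
"XXXOXXOX": -0.3809,
"XXXOXXXO": 1.2464,
"XXXOXXXX": 0.5466,
"XXXXOOOOO": -1.4962,
"XXXXOOOOX": -2.014,
"XXXXOOOXO": -0.2522,
"XXXXOOOXX": -0.6811,
"XXXXOOXOO": -0.5044,
"XXXXOOXOX": -0.9538,
"XXXXOOXXO": 0.7524,
"XXXXOOXXX": 0.2631,
"XXXXOXOOO": -0.7582,
"XXXXOXOOX": -1.2476,
"XXXXOXOXO": 0.453,
"XXXXOXOXX": -0.0398,
"XXXXOXXOO": 0.1421,
"XXXXOXXOX": -0.3809,
"XXXXOXXXO": 1.2464,
"XXXXOXXXX": 0.5466,
"XXXXXOOOO": -1.0012,
"XXXXXOOOX": -1.549,
"XXXXXOOXO": 0.1421,
"XXXXXOOXX": -0.3809,
"XXXXXOXOO": -0.1819,
"XXXXXOXOX": -0.741,
"XXXXXOXXO": 0.8597,
"XXXXXOXXX": 0.1537,
"XXXXXXOOO": -0.5062,
"XXXXXXOOX": -1.1403,
"XXXXXXOXO": 0.4321,
"XXXXXXOXX": -0.3153,
"XXXXXXXOO": -0.028,
"XXXXXXXOX": -0.894,
"XXXXXXXXO": 0.3771
}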